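"""Cosegregation and association genetics for a dominant presence/absence marker.

Covers the genetic validation chain for an S-haplotype-specific gene:

* counting recombinants in a testcross (short S/s x long s/s; only the
  short parent's meioses are informative since the long parent is
  homozygous at the S-locus),
* exact one-sided Clopper-Pearson upper bounds on the recombination
  fraction, mapped to centimorgans,
* Fisher's exact test for marker-morph association in a landrace panel, and
* a deterministic recurrence for the decay of marker-morph association
  under heteromorphic self-incompatibility, where every mating is between
  a short-styled S/s plant and a long-styled s/s plant.

Decay model state.  ``a`` is the frequency of the marker-positive allele on
S haplotypes, ``b`` on the s haplotypes carried by short-styled plants, and
``c`` on the s haplotypes of long-styled plants.  Recombination is only
observable in the S/s heterozygote, giving the update

    a' = (1-r) a + r b
    b' = c
    c' = 1/2 [(1-r) b + r a] + 1/2 c

with the allele-frequency invariant a/4 + b/4 + c/2 (S haplotypes are 1/4
of all haplotypes, short-plant s haplotypes another 1/4, long-plant s
haplotypes 1/2).  From the study's initial condition (a, b, c) = (1, 0, 0)
the state converges for any r > 0 to (1/4, 1/4, 1/4), where the fraction
of marker-positive plants is 7/16 in both morphs and the association is
fully decayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinkageResult",
    "DecayState",
    "count_recombinants",
    "recombination_upper_bound",
    "association_exact_test",
    "association_decay_step",
    "association_decay_trajectory",
    "morph_marker_table",
]

_SHORT = {"s", "short", "S"}
_LONG = {"l", "long", "L"}
_PRESENT = {"1", "present", "+", "true", "yes"}
_ABSENT = {"0", "absent", "-", "false", "no"}


def _norm_morph(value) -> str | None:
    v = str(value).strip()
    if v in ("S", "s") or v.lower() == "short":
        return "S"
    if v in ("L", "l") or v.lower() == "long":
        return "L"
    return None


def _norm_marker(value) -> int | None:
    v = str(value).strip().lower()
    if v in _PRESENT or v == "1":
        return 1
    if v in _ABSENT or v == "0":
        return 0
    return None


def _normalized(table: pd.DataFrame) -> pd.DataFrame:
    morph = table["morph"].map(_norm_morph)
    marker = table["marker"].map(_norm_marker)
    ok = morph.notna() & marker.notna()
    bad = int((~ok).sum())
    if bad:
        warnings.warn(f"{bad} record(s) with missing/invalid fields rejected")
    return pd.DataFrame({"morph": morph[ok], "marker": marker[ok].astype(int)})


def count_recombinants(table: pd.DataFrame) -> tuple[int, int]:
    """Count informative meioses and recombinants in a testcross table.

    With the marker in coupling with S, recombinant offspring are exactly
    the (short, marker absent) and (long, marker present) records.  Rows
    with unparseable morph or marker values are rejected with a warning.
    """
    t = _normalized(table)
    n = len(t)
    x = int(((t["morph"] == "S") != (t["marker"] == 1)).sum())
    return n, x


@dataclass
class LinkageResult:
    n_meioses: int
    n_recombinants: int
    r_hat: float
    r_upper: float
    confidence: float
    cM_upper: float
    map_function: str = "direct"


def _to_cM(r: float, map_function: str) -> float:
    if map_function == "direct":
        return 100.0 * r
    if map_function == "haldane":
        return float("inf") if r >= 0.5 else -50.0 * np.log(1 - 2 * r)
    if map_function == "kosambi":
        return float("inf") if r >= 0.5 else 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    raise ValueError(f"unknown map function {map_function!r}")


def recombination_upper_bound(
    n_meioses: int,
    n_recombinants: int,
    confidence: float = 0.95,
    map_function: str = "direct",
) -> LinkageResult:
    """Exact one-sided upper confidence bound on the recombination fraction.

    Clopper-Pearson: the bound is the beta quantile
    ``Beta(confidence; x+1, n-x)``; with zero recombinants this reduces to
    the closed form ``1 - (1-confidence)^(1/n)``.  The point estimate is
    capped at 0.5 (free recombination) with a warning.  Map distance uses
    cM = 100 r by default — at the sub-centimorgan distances of interest
    Haldane/Kosambi corrections are negligible, but both are available.
    """
    if n_meioses <= 0:
        raise ValueError("need at least one informative meiosis")
    if not 0 <= n_recombinants <= n_meioses:
        raise ValueError("recombinant count outside [0, n]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    r_hat = n_recombinants / n_meioses
    if r_hat > 0.5:
        warnings.warn("observed recombinant fraction exceeds 0.5; capped")
        r_hat = min(r_hat, 1.0)
    if n_recombinants == n_meioses:
        r_upper = 1.0
    else:
        r_upper = float(
            stats.beta.ppf(confidence, n_recombinants + 1, n_meioses - n_recombinants)
        )
    return LinkageResult(
        n_meioses=n_meioses,
        n_recombinants=n_recombinants,
        r_hat=r_hat,
        r_upper=r_upper,
        confidence=confidence,
        cM_upper=_to_cM(r_upper, map_function),
        map_function=map_function,
    )


def morph_marker_table(panel: pd.DataFrame) -> np.ndarray:
    """2x2 contingency table [[short+, short-], [long+, long-]]."""
    norm = _normalized(panel)
    t = np.zeros((2, 2), dtype=int)
    for (morph, marker), count in norm.value_counts().items():
        t[0 if morph == "S" else 1, 0 if marker == 1 else 1] = count
    return t


def association_exact_test(panel) -> float:
    """Two-sided Fisher exact probability of the observed morph x marker table.

    Accepts either a per-plant DataFrame (columns morph, marker) or a 2x2
    table.  The p-value is computed by direct hypergeometric enumeration:
    the sum of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    if isinstance(panel, pd.DataFrame) and "morph" in panel.columns:
        table = morph_marker_table(panel)
    else:
        table = np.asarray(panel, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a = int(table[0, 0])
    r1 = int(table[0].sum())
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("empty margin; association test degenerate, p = 1")
        return 1.0
    rv = stats.hypergeom(n, r1, c1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class DecayState:
    """Marker-positive allele frequencies on the three haplotype classes."""

    a: float  # on S haplotypes (short plants)
    b: float  # on s haplotypes of short plants
    c: float  # on s haplotypes of long plants
    generation: int = 0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a frequency in [0, 1]")

    @property
    def conserved(self) -> float:
        """Population frequency of the marker allele: a/4 + b/4 + c/2."""
        return self.a / 4 + self.b / 4 + self.c / 2

    @property
    def Sx(self) -> float:
        """Fraction of short-styled plants carrying the marker."""
        return 1.0 - (1.0 - self.a) * (1.0 - self.b)


PAPER_INIT = DecayState(a=1.0, b=0.0, c=0.0)
"""Initial population: short plants are marker+S / marker-s heterozygotes,
long plants marker-s homozygotes, in equal numbers."""


def association_decay_step(state: DecayState, r: float) -> DecayState:
    """One generation of obligate intermorph random mating."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    a, b, c = state.a, state.b, state.c
    short_s_gamete = (1 - r) * b + r * a
    return DecayState(
        a=(1 - r) * a + r * b,
        b=c,
        c=0.5 * short_s_gamete + 0.5 * c,
        generation=state.generation + 1,
    )


def association_decay_trajectory(
    r: float, n_generations: int, init: DecayState = PAPER_INIT
) -> pd.DataFrame:
    """Per-generation marker carrier frequencies in the two morphs.

    ``Sx`` is the fraction of short-styled and ``Lx`` of long-styled plants
    carrying the marker.  For offspring generations Lx pairs the short
    parent's s gamete (marker frequency (1-r)b + ra) with the long parent's
    (frequency c) exactly; at generation 0 long plants carry two haplotypes
    of the initial class c.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    state = replace(init, generation=0)
    rows = [
        {
            "generation": 0,
            "a": state.a,
            "b": state.b,
            "c": state.c,
            "Sx": state.Sx,
            "Lx": 1.0 - (1.0 - state.c) ** 2,
        }
    ]
    for _ in range(n_generations):
        prev = state
        state = association_decay_step(state, r)
        short_s_gamete = (1 - r) * prev.b + r * prev.a
        rows.append(
            {
                "generation": state.generation,
                "a": state.a,
                "b": state.b,
                "c": state.c,
                "Sx": state.Sx,
                "Lx": 1.0 - (1.0 - short_s_gamete) * (1.0 - prev.c),
            }
        )
    return pd.DataFrame(rows)
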