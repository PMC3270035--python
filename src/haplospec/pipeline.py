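"""Config-driven pipeline runner with a reproducibility manifest.

A pipeline config (YAML or dict) names an output directory and an ordered
list of stages; each stage writes its own outputs and contributes a manifest
entry with its parameters, output checksums and summary counts.  Re-running
the same config on the same inputs reproduces identical output checksums —
every stochastic stage takes an explicit seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from . import evolution, genetics, io, simulate, subtraction

__all__ = ["RunManifest", "load_config", "run_pipeline"]


@dataclass
class RunManifest:
    version: str
    timestamp: str
    config_hash: str
    stages: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def _stage_simulate_transcriptomes(params: dict, out_dir: Path) -> dict:
    spec = simulate.TranscriptomeSpec(
        n_shared_genes=int(params.get("n_shared_genes", 50)),
        n_s_specific_genes=int(params.get("n_s_specific_genes", 5)),
        gene_length_range=tuple(params.get("gene_length_range", (200, 3000))),
        allelic_snp_rate=float(params.get("allelic_snp_rate", 0.001)),
        seed=int(params.get("seed", 0)),
    )
    short, long_, truth = simulate.generate_transcriptomes(spec)
    io.write_fasta(short, out_dir / "short_morph.fasta")
    io.write_fasta(long_, out_dir / "long_morph.fasta")
    io.write_table(truth, out_dir / "truth.tsv")
    return {
        "outputs": ["short_morph.fasta", "long_morph.fasta", "truth.tsv"],
        "summary": {"n_short": len(short), "n_long": len(long_)},
    }


def _stage_simulate_reads(params: dict, out_dir: Path) -> dict:
    transcripts = io.read_fasta(out_dir / params.get("input", "long_morph.fasta"))
    n_pairs = params.get("n_pairs")
    if n_pairs is None:
        coverage = float(params.get("coverage", 15.0))
        read_length = int(params.get("read_length", 50))
        total = sum(len(r.seq) for r in transcripts)
        n_pairs = int(coverage * total / (2 * read_length)) + 1
    sim = simulate.ReadSimParams(
        n_pairs=int(n_pairs),
        read_length=int(params.get("read_length", 50)),
        per_base_error=float(params.get("per_base_error", 0.0)),
        strand_model=params.get("strand_model", "both-strands"),
        seed=int(params.get("seed", 0)),
    )
    reads = simulate.simulate_reads(transcripts, sim)
    prefix = params.get("prefix", "reads")
    io.write_fastq_pair(reads, out_dir / f"{prefix}_1.fq", out_dir / f"{prefix}_2.fq")
    return {
        "outputs": [f"{prefix}_1.fq", f"{prefix}_2.fq"],
        "summary": {"n_pairs": len(reads)},
    }


def _stage_subtract(params: dict, out_dir: Path) -> dict:
    contigs = io.read_fasta(out_dir / params.get("contigs", "short_morph.fasta"))
    read_files = params.get("reads", ["reads_1.fq", "reads_2.fq"])
    reads = io.read_fastq(*[out_dir / f for f in read_files])
    report, retained = subtraction.subtract(
        contigs,
        reads,
        k=int(params.get("k", 32)),
        canonical=bool(params.get("canonical", True)),
        max_shared_fraction=float(params.get("max_shared_fraction", 0.0)),
    )
    io.write_table(report, out_dir / "subtraction_report.tsv")
    io.write_fasta(retained, out_dir / "retained.fasta")
    return {
        "outputs": ["subtraction_report.tsv", "retained.fasta"],
        "summary": report.attrs["summary"],
    }


def _stage_simulate_cross(params: dict, out_dir: Path) -> dict:
    cross = simulate.simulate_testcross(
        simulate.CrossSimParams(
            n_plants=int(params.get("n_plants", 1373)),
            r=float(params.get("r", 0.0)),
            seed=int(params.get("seed", 0)),
        )
    )
    io.write_table(cross[["plant_id", "morph", "marker"]], out_dir / "cross.tsv")
    io.write_table(cross, out_dir / "cross_truth.tsv")
    return {
        "outputs": ["cross.tsv", "cross_truth.tsv"],
        "summary": {"n_plants": len(cross)},
    }


def _stage_linkage(params: dict, out_dir: Path) -> dict:
    table = io.read_table(out_dir / params.get("table", "cross.tsv"))
    n, x = genetics.count_recombinants(table)
    result = genetics.recombination_upper_bound(
        n, x, confidence=float(params.get("confidence", 0.95))
    )
    payload = asdict(result)
    (out_dir / "linkage.json").write_text(json.dumps(payload, indent=2))
    return {"outputs": ["linkage.json"], "summary": payload}


def _stage_assoc(params: dict, out_dir: Path) -> dict:
    table = io.read_table(out_dir / params.get("table", "cross.tsv"))
    p = genetics.association_exact_test(table)
    payload = {"p_value": p}
    (out_dir / "assoc.json").write_text(json.dumps(payload, indent=2))
    return {"outputs": ["assoc.json"], "summary": payload}


def _stage_decay(params: dict, out_dir: Path) -> dict:
    traj = genetics.association_decay_trajectory(
        r=float(params.get("r", 0.01)),
        n_generations=int(params.get("n_generations", 100)),
    )
    io.write_table(traj, out_dir / "decay_trajectory.tsv")
    return {
        "outputs": ["decay_trajectory.tsv"],
        "summary": {"final_Sx": traj["Sx"].iloc[-1], "final_Lx": traj["Lx"].iloc[-1]},
    }


def _stage_distances(params: dict, out_dir: Path) -> dict:
    aln_set = io.read_fasta(out_dir / params["alignment"])
    alignment = {c.id: c.seq for c in aln_set}
    mode = params.get("mode", "p")
    if mode == "p":
        dm = evolution.p_distance_matrix(
            alignment, deletion=params.get("deletion", "complete")
        )
        io.write_table(dm.to_dataframe().reset_index(), out_dir / "distances.tsv")
        summary = {"mode": "p", "n": len(dm.labels)}
    elif mode == "ng":
        rows = []
        labels = list(alignment)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                res = evolution.ng_distance(
                    alignment[a],
                    alignment[b],
                    R=float(params.get("R", 1.0)),
                    correction=params.get("correction", "jukes_cantor"),
                )
                rows.append({"seq1": a, "seq2": b, "dS": res.dS, "dN": res.dN})
        import pandas as pd

        io.write_table(pd.DataFrame(rows), out_dir / "distances.tsv")
        summary = {"mode": "ng", "n_pairs": len(rows)}
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return {"outputs": ["distances.tsv"], "summary": summary}


def _stage_tree(params: dict, out_dir: Path) -> dict:
    aln_set = io.read_fasta(out_dir / params["alignment"])
    alignment = {c.id: c.seq for c in aln_set}
    n_boot = int(params.get("bootstrap", 0))
    if n_boot > 0:
        tree, _ = evolution.bootstrap_support(
            alignment, n_replicates=n_boot, seed=int(params.get("seed", 0))
        )
    else:
        tree = evolution.neighbor_joining(evolution.p_distance_matrix(alignment))
    io.write_newick(tree, out_dir / "tree.nwk")
    total = evolution.sum_branch_lengths(tree)
    return {
        "outputs": ["tree.nwk"],
        "summary": {"total_branch_length": total, "bootstrap": n_boot},
    }


def _stage_date(params: dict, out_dir: Path) -> dict:
    rate = params.get("rate")
    if rate is None:
        rate = evolution.calibrate_rate(
            float(params["calibration_distance"]), float(params["split_time"])
        )
    payload = {"rate_per_site_per_year": float(rate)}
    if "distance" in params:
        payload["divergence_years"] = evolution.divergence_time(
            float(params["distance"]), float(rate)
        )
    if "tree_length" in params:
        payload["coevolution_years"] = evolution.coevolution_time(
            float(params["tree_length"]), float(rate)
        )
    (out_dir / "dating.json").write_text(json.dumps(payload, indent=2))
    return {"outputs": ["dating.json"], "summary": payload}


_STAGES = {
    "simulate_transcriptomes": _stage_simulate_transcriptomes,
    "simulate_reads": _stage_simulate_reads,
    "subtract": _stage_subtract,
    "simulate_cross": _stage_simulate_cross,
    "linkage": _stage_linkage,
    "assoc": _stage_assoc,
    "decay": _stage_decay,
    "distances": _stage_distances,
    "tree": _stage_tree,
    "date": _stage_date,
}


def run_pipeline(config: dict, out_dir=None) -> RunManifest:
    """Execute the configured stages in order and emit a manifest.

    ``config`` holds ``out_dir`` (unless overridden) and ``stages``, a list
    of ``{stage: <name>, ...params}`` mappings.  A stage failure aborts the
    run with the partial manifest attached to the raised exception.
    """
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config_hash=config_hash,
    )
    for entry in config.get("stages", []):
        entry = dict(entry)
        name = entry.pop("stage")
        if name not in _STAGES:
            raise ValueError(f"unknown pipeline stage {name!r}")
        try:
            result = _STAGES[name](entry, out_dir)
        except Exception as exc:
            exc.partial_manifest = manifest
            raise
        result["stage"] = name
        result["params"] = entry
        result["checksums"] = {
            f: _sha256(out_dir / f) for f in result.get("outputs", [])
        }
        manifest.stages.append(result)
    manifest.to_json(out_dir / "manifest.json")
    return manifest
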