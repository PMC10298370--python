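"""End-to-end orchestration: manifest in, staged artifact tree out.

Stages communicate through on-disk TSV/JSON so any intermediate can be
inspected or resumed, and a rerun with the same config and inputs is
bit-identical for every deterministic stage. The full configuration
(thresholds, seed) is serialized into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon_io import (
    load_manifest,
    load_reads,
    load_references,
    write_table,
)
from .core_discovery import (
    CoreConfig,
    cores_frame,
    enumerate_cores,
    maximal_cores,
    track_cores,
    trajectories_frame,
)
from .epiallele import build_matrix, call_methylation, tabulate
from .identity_tree import build_tree, distance_matrix, profile_from_cores
from .popstats import profiles_frame
from .read_qc import QCConfig, run_qc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

STAGES = ("qc", "epialleles", "stats", "cores", "trajectories", "tree")


@dataclass
class RunConfig:
    manifest: str
    references: str
    out_dir: str
    qc: QCConfig = field(default_factory=QCConfig)
    core: CoreConfig = field(default_factory=CoreConfig)
    maximal_f_tol: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QCConfig(**raw.pop("qc", {}))
        core = CoreConfig(**raw.pop("core", {}))
        return cls(qc=qc, core=core, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def run_all(config: RunConfig) -> dict:
    """Run qc -> epialleles -> stats -> cores -> trajectories -> tree.

    Returns a summary dict; on stage failure a FAILED marker file is left in
    the output directory, partial outputs are retained, and the exception
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1) + "\n")
    try:
        return _run_stages(config, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run_stages(config: RunConfig, out: Path) -> dict:
    manifest = load_manifest(config.manifest)
    if not manifest:
        raise ValueError(f"manifest {config.manifest} lists no samples")
    refs = load_references(config.references)
    for d in STAGES:
        (out / d).mkdir(exist_ok=True)

    tables = {}
    cores_by_sample = {}
    sample_meta = {}
    import pandas as pd

    qc_rows = []
    for entry in manifest:
        ref = refs[entry.reference_name]
        reads = load_reads(entry.read_file)
        retained, report = run_qc(reads, ref, config.qc)
        calls = [call_methylation(aln, ref) for _, aln in retained]
        matrix, n_amb = build_matrix(calls, ref.cpg_labels, entry.sample_id)
        report.record_ambiguous_drops(n_amb)
        qc_rows.append({"sample": entry.sample_id, **report.as_dict()})
        table = tabulate(matrix)
        table.sample_id = entry.sample_id
        tables[entry.sample_id] = table
        sample_meta[entry.sample_id] = entry
        write_table(table.to_frame(), out / "epialleles" / f"{entry.sample_id}.tsv")

        cores = enumerate_cores(table, config.core)
        maximal = maximal_cores(cores, config.maximal_f_tol)
        cores_by_sample[entry.sample_id] = maximal
        write_table(cores_frame(cores, entry.sample_id),
                    out / "cores" / f"{entry.sample_id}.all.tsv")
        write_table(cores_frame(maximal, entry.sample_id),
                    out / "cores" / f"{entry.sample_id}.maximal.tsv")
        logger.info("%s: %d/%d reads retained, %d maximal cores",
                    entry.sample_id, report.n_retained, report.n_input, len(maximal))

    write_table(pd.DataFrame(qc_rows), out / "qc" / "qc_report.tsv")
    nonempty = [t for t in tables.values() if t.n_total > 0]
    if nonempty:
        write_table(profiles_frame(nonempty), out / "stats" / "profiles.tsv")

    # trajectories per amplicon across its declared time order
    by_ref: dict[str, list[str]] = {}
    for sid, entry in sample_meta.items():
        by_ref.setdefault(entry.reference_name, []).append(sid)
    n_traj = 0
    for ref_name, sids in by_ref.items():
        order = [t for t in sample_meta[sids[0]].time_order
                 if any(sample_meta[s].time_label == t for s in sids)]
        if len(order) < 2:
            continue
        cores_by_time = {sample_meta[s].time_label: cores_by_sample[s] for s in sids}
        tables_by_time = {sample_meta[s].time_label: tables[s] for s in sids}
        trajectories = track_cores(cores_by_time, tables_by_time, order)
        n_traj += len(trajectories)
        write_table(trajectories_frame(trajectories),
                    out / "trajectories" / f"{ref_name}.tsv")

    profiles = [
        profile_from_cores(sid, cores_by_sample[sid])
        for sid in sorted(cores_by_sample)
        if cores_by_sample[sid]
    ]
    newick = None
    if len(profiles) >= 2:
        newick = build_tree(distance_matrix(profiles))
        (out / "tree" / "core_tree.nwk").write_text(newick + "\n")

    return {
        "n_samples": len(manifest),
        "n_trajectories": n_traj,
        "tree": newick,
        "out_dir": str(out),
    }
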