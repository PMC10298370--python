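"""Synthetic bisulfite amplicon populations with known ground truth.

The generator emulates the statistical structure of targeted bisulfite
amplicon sequencing of a differentiating cell population: molecules fall
into one or more epiallele families, each defined by a planted core of CpGs
methylated with high per-member fidelity, on top of independently
fluctuating background methylation at every other CpG; non-family molecules
methylate independently at background rates throughout. Reads are rendered
through an in-silico bisulfite reaction with imperfect conversion of
non-CpG cytosines (default 98.5%, matching the 98-99% rate typical of a
successful treatment), uniform substitution sequencing errors, and a small
rate of ambiguous (N) base calls at CpGs. Read length equals the amplicon
length, as in amplicon sequencing; reads are not fragmented.

Five built-in amplicon designs mirror the promoter panels the pipeline is
aimed at (NANOG and DDO with 6 CpGs, TUBB3 with 18, BDNF with 13, GFAP with
12, with the published TSS-relative labels for the landmark CpGs); their
actual sequences are generated pseudo-randomly since primer/amplicon
sequences are user-supplied in real use.

Everything is reproducible from a single integer seed: the same seed gives
byte-identical read files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import zlib

import numpy as np
import pandas as pd

from .amplicon_io import AmpliconReference, ReadRecord, SampleManifest, write_reads
from .epiallele import MethMatrix

__all__ = [
    "SynthConfig",
    "TimeSeriesConfig",
    "make_reference",
    "sample_patterns",
    "render_reads",
    "simulate_timecourse",
    "expected_joint_frequency",
    "ddo_timecourse",
    "nanog_timecourse",
    "AMPLICON_DESIGNS",
]

# (number of CpGs, TSS-relative labels). Landmark labels are the published
# ones (e.g. the DDO 105-138-150-226-293-343 panel); the rest fill the span.
AMPLICON_DESIGNS: dict[str, tuple[int, ...]] = {
    "DDO": (105, 138, 150, 226, 293, 343),
    "NANOG": (80, 141, 198, 260, 365, 375),
    "TUBB3": (22, 35, 51, 70, 92, 115, 131, 149, 168, 190, 211, 233, 252, 274, 295, 310, 330, 352),
    "BDNF": (40, 58, 81, 82, 83, 110, 135, 160, 188, 215, 247, 280, 310),
    "GFAP": (35, 84, 109, 140, 168, 197, 225, 252, 278, 304, 330, 355),
}

_PRIMER_LEN = 24
_MARGIN = 30  # offset of the first CpG from the amplicon start


def make_reference(name: str, seed: int = 0, labels: Sequence[int] | None = None) -> AmpliconReference:
    """Build a seeded amplicon reference for one of the built-in designs.

    CpGs sit at offsets ``_MARGIN + (label - min(label))``; the rest of the
    sequence is random with no CpG outside the annotated offsets, so every
    annotated CpG is the only CpG context present.
    """
    if labels is None:
        if name not in AMPLICON_DESIGNS:
            raise ValueError(
                f"unknown design {name!r}; choose from {sorted(AMPLICON_DESIGNS)} or pass labels"
            )
        labels = AMPLICON_DESIGNS[name]
    labels = tuple(int(l) for l in labels)
    # labels are names, not coordinates: adjacent labels (e.g. the BDNF
    # 81/82/83 run) still need >= 2 nt between CpG cytosines
    offsets_list: list[int] = []
    for l in labels:
        off = _MARGIN + (l - min(labels))
        if offsets_list and off < offsets_list[-1] + 2:
            off = offsets_list[-1] + 2
        offsets_list.append(off)
    offsets = tuple(offsets_list)
    length = max(offsets) + 2 + 2 * _MARGIN
    rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
    seq = rng.choice(list("ACGT"), size=length).tolist()
    for off in offsets:
        seq[off], seq[off + 1] = "C", "G"
    # scrub accidental CpGs so the coordinate map is exhaustive
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in offsets:
            seq[i + 1] = "A"
    sequence = "".join(seq)
    forward = sequence[:_PRIMER_LEN]
    reverse = _revcomp(sequence[-_PRIMER_LEN:])
    return AmpliconReference(
        name=name,
        sequence=sequence,
        forward_primer=forward,
        reverse_primer=reverse,
        cpg_offsets=offsets,
        cpg_labels=labels,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic sample.

    ``families`` is a list of (core label set, prevalence) components with
    prevalences summing to at most 1; the remainder of the population is
    core-free background. ``core_fidelity`` is the chance a family molecule
    is methylated at each of its core CpGs; ``background_marginals`` (scalar
    or per-CpG) drives every other methylation event.
    """

    reference: AmpliconReference
    n_reads: int = 2000
    families: tuple[tuple[tuple[int, ...], float], ...] = ()
    core_fidelity: float = 0.95
    background_marginals: float | tuple[float, ...] = 0.1
    conversion_efficiency: float = 0.985
    seq_error_rate: float = 0.001
    ambiguous_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total_prev = sum(p for _, p in self.families)
        if not 0 <= total_prev <= 1 + 1e-12:
            raise ValueError(f"family prevalences sum to {total_prev}")
        for labels, prev in self.families:
            if not 0 <= prev <= 1:
                raise ValueError(f"prevalence {prev} outside [0, 1]")
            unknown = set(labels) - set(self.reference.cpg_labels)
            if unknown:
                raise ValueError(f"core labels {sorted(unknown)} not on the reference")
        for p in (self.core_fidelity, self.conversion_efficiency,
                  self.seq_error_rate, self.ambiguous_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")

    @classmethod
    def single_core(
        cls,
        reference: AmpliconReference,
        core_labels: Sequence[int],
        core_prevalence: float,
        **kwargs,
    ) -> "SynthConfig":
        fams = (
            ((tuple(int(l) for l in core_labels), float(core_prevalence)),)
            if core_labels and core_prevalence > 0
            else ()
        )
        return cls(reference=reference, families=fams, **kwargs)

    def marginals_array(self) -> np.ndarray:
        k = self.reference.n_cpgs
        bg = self.background_marginals
        arr = np.full(k, bg, dtype=float) if np.isscalar(bg) else np.asarray(bg, dtype=float)
        if arr.shape != (k,):
            raise ValueError(f"background_marginals length != {k}")
        return arr


@dataclass(frozen=True)
class TimeSeriesConfig:
    """An ordered series of per-time synthetic samples on one amplicon."""

    time_labels: tuple[str, ...]
    base: SynthConfig
    overrides: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.overrides:
            if t not in self.time_labels:
                raise ValueError(f"override for unknown time {t!r}")

    def config_at(self, time: str, seed: int) -> SynthConfig:
        if time not in self.time_labels:
            raise ValueError(f"unknown time {time!r}")
        return replace(self.base, seed=seed, **self.overrides.get(time, {}))


def sample_patterns(cfg: SynthConfig) -> tuple[MethMatrix, np.ndarray]:
    """Draw the binary methylation matrix and the molecule family assignment.

    Families are drawn once per molecule (index into ``cfg.families``; -1 is
    background); family molecules methylate at ``core_fidelity`` on their
    core CpGs and at the background marginal elsewhere.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    k = cfg.reference.n_cpgs
    n = cfg.n_reads
    bg = cfg.marginals_array()
    probs = np.tile(bg, (n, 1))
    prevs = np.array([p for _, p in cfg.families])
    cut = np.concatenate([[0.0], np.cumsum(prevs)])
    u = rng.random(n)
    family = np.full(n, -1, dtype=int)
    for fi, (labels, _) in enumerate(cfg.families):
        members = (u >= cut[fi]) & (u < cut[fi + 1])
        family[members] = fi
        cols = [cfg.reference.cpg_labels.index(l) for l in labels]
        probs[np.ix_(members, cols)] = cfg.core_fidelity
    data = (rng.random((n, k)) < probs).astype(np.uint8)
    ids = tuple(
        f"{cfg.reference.name}_read{i:05d}|fam={family[i]}" for i in range(n)
    )
    matrix = MethMatrix(
        sample_id=cfg.reference.name, cpg_labels=cfg.reference.cpg_labels,
        data=data, read_ids=ids,
    )
    return matrix, family


def render_reads(matrix: MethMatrix, cfg: SynthConfig) -> list[ReadRecord]:
    """Render a methylation matrix into bisulfite-converted reads.

    Per molecule: methylated CpG cytosines stay C, unmethylated ones read T;
    every non-CpG C converts to T with probability ``conversion_efficiency``
    (a conversion failure leaves C); substitution errors hit any base at
    ``seq_error_rate``; each CpG is replaced by N with ``ambiguous_rate``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ref = cfg.reference
    n, k = matrix.data.shape
    base = np.frombuffer(ref.sequence.encode(), dtype="S1")
    reads = np.tile(base, (n, 1)).astype("U1")
    seq = ref.sequence
    non_cpg_c = np.array(
        [i for i, b in enumerate(seq)
         if b == "C" and (i == len(seq) - 1 or seq[i + 1] != "G")],
        dtype=int,
    )
    offsets = np.array(ref.cpg_offsets, dtype=int)

    if non_cpg_c.size:
        conv = rng.random((n, non_cpg_c.size)) < cfg.conversion_efficiency
        block = reads[:, non_cpg_c]
        block[conv] = "T"
        reads[:, non_cpg_c] = block

    cpg_block = np.where(matrix.data.astype(bool), "C", "T")
    reads[:, offsets] = cpg_block

    if cfg.seq_error_rate > 0:
        err = rng.random(reads.shape) < cfg.seq_error_rate
        shifts = rng.integers(1, 4, size=int(err.sum()))
        lut = np.array(list("ACGT"))
        cur = np.searchsorted(lut, reads[err])
        reads[err] = lut[(cur + shifts) % 4]

    if cfg.ambiguous_rate > 0:
        amb = rng.random((n, k)) < cfg.ambiguous_rate
        block = reads[:, offsets]
        block[amb] = "N"
        reads[:, offsets] = block

    ids = matrix.read_ids or tuple(f"{ref.name}_read{i:05d}" for i in range(n))
    return [
        ReadRecord(id=ids[i], sequence="".join(reads[i])) for i in range(n)
    ]


def expected_joint_frequency(cfg: SynthConfig, labels: Sequence[int]) -> float:
    """Closed-form expected fraction of molecules methylated at all ``labels``.

    Mixture over families: a family molecule is methylated at a member CpG
    with the core fidelity and at any other CpG with its background
    marginal; background molecules use the marginals throughout.
    """
    bg = cfg.marginals_array()
    idx = [cfg.reference.cpg_labels.index(int(l)) for l in labels]
    total = 0.0
    rest = 1.0
    for fam_labels, prev in cfg.families:
        rest -= prev
        p = 1.0
        for l, i in zip(labels, idx):
            p *= cfg.core_fidelity if int(l) in fam_labels else bg[i]
        total += prev * p
    total += rest * float(np.prod(bg[idx]))
    return total


def _child_seed(master: int, index: int) -> int:
    return int((master * 1_000_003 + 7_919 * (index + 1)) % (2**31))


def simulate_timecourse(
    tsc: TimeSeriesConfig, out_dir: str | Path
) -> tuple[list[SampleManifest], dict]:
    """Write one FASTA per time point plus a manifest TSV and truth JSON.

    Per-time seeds derive deterministically from the base seed and the time
    index, so the whole time course is reproducible from one integer.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = tsc.base.reference.name
    manifest: list[SampleManifest] = []
    truth: dict = {"amplicon": name, "times": {}}
    for i, t in enumerate(tsc.time_labels):
        cfg = tsc.config_at(t, _child_seed(tsc.base.seed, i))
        matrix, family = sample_patterns(cfg)
        reads = render_reads(matrix, cfg)
        fasta = out / f"{name}_{t}.fasta"
        write_reads(reads, fasta, "fasta")
        manifest.append(
            SampleManifest(
                sample_id=f"{name}_{t}",
                time_label=t,
                read_file=str(fasta),
                reference_name=name,
                time_order=tsc.time_labels,
            )
        )
        truth["times"][t] = {
            "seed": cfg.seed,
            "n_reads": cfg.n_reads,
            "families": [
                {"core": list(labels), "prevalence": prev}
                for labels, prev in cfg.families
            ],
            "core_fidelity": cfg.core_fidelity,
            "background_marginals": list(cfg.marginals_array()),
            "conversion_efficiency": cfg.conversion_efficiency,
            "n_family_reads": [int((family == fi).sum()) for fi in range(len(cfg.families))],
        }
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "time_label": m.time_label,
                "read_file": m.read_file,
                "reference_name": m.reference_name,
            }
            for m in manifest
        ]
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return manifest, truth


def ddo_timecourse(
    seed: int = 0,
    n_reads: int = 2000,
    reference: AmpliconReference | None = None,
) -> TimeSeriesConfig:
    """DDO-like transient schedule: core 105-138-150 rising to a T4 peak,
    then returning toward baseline at T8-T14."""
    ref = reference or make_reference("DDO", seed=seed)
    core = (105, 138, 150)
    prevalences = {"T0": 0.3, "T2": 0.4, "T4": 0.7, "T8": 0.4, "T14": 0.3}
    base = SynthConfig.single_core(ref, core, prevalences["T0"], n_reads=n_reads, seed=seed)
    overrides = {
        t: {"families": ((core, p),)} for t, p in prevalences.items()
    }
    return TimeSeriesConfig(("T0", "T2", "T4", "T8", "T14"), base, overrides)


def nanog_timecourse(
    seed: int = 0,
    n_reads: int = 2000,
    reference: AmpliconReference | None = None,
) -> TimeSeriesConfig:
    """NANOG-like gain schedule: no core early, core 365-375 appearing at T8
    and consolidating at T14 while background methylation creeps up."""
    ref = reference or make_reference("NANOG", seed=seed)
    core = (365, 375)
    base = SynthConfig(reference=ref, n_reads=n_reads, seed=seed)
    overrides = {
        "T0": {"families": (), "background_marginals": 0.05},
        "T2": {"families": (), "background_marginals": 0.1},
        "T4": {"families": (), "background_marginals": 0.15},
        "T8": {"families": ((core, 0.5),), "background_marginals": 0.2},
        "T14": {"families": ((core, 0.6),), "background_marginals": 0.3},
    }
    return TimeSeriesConfig(("T0", "T2", "T4", "T8", "T14"), base, overrides)
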