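"""Read QC: alignment to the bisulfite-converted reference and retention filters.

Each merged read is aligned semi-globally (reference overhangs unpenalized)
against the bisulfite-converted amplicon, with CpG-context cytosines treated
as C/T-ambiguous: a CpG reads C when methylated and T when not, so neither
base is an error there. Four retention filters are then applied in a fixed
order -- length, primer similarity, bisulfite conversion efficiency, aligned
fraction -- and a per-filter attrition report is kept. Each read is counted
against the first filter it fails, so the report columns always sum to the
input count. All thresholds are inclusive (>=).

Conversion efficiency is the per-read fraction of non-CpG-context reference
cytosines read as T within the aligned span; its mean over retained reads
estimates the sample's bisulfite conversion rate (expected ~98-99% for a
successful treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .amplicon_io import AmpliconReference, ReadRecord, bisulfite_convert

__all__ = [
    "Alignment",
    "QCConfig",
    "QCReport",
    "NonAmpliconError",
    "align_read",
    "length_filter",
    "primer_filter",
    "conversion_filter",
    "alignment_filter",
    "run_qc",
]

# Y marks a CpG-context C in the converted reference: matched by C and T.
_ALPHABET = "ACGTYN"


class NonAmpliconError(ValueError):
    """Read rejected outright as non-amplicon (e.g. grossly over-long)."""


@dataclass(frozen=True)
class QCConfig:
    """Thresholds and alignment scoring for the QC stage."""

    min_length_frac: float = 0.5
    min_primer_sim: float = 0.80
    min_conversion: float = 0.98
    min_aligned_frac: float = 0.60
    match_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    # optional absolute length window (e.g. 400-500 nt); None disables
    length_window: tuple[int, int] | None = None


@dataclass
class Alignment:
    """A read's semi-global alignment against its converted reference.

    ``aligned_pairs`` holds one (read_offset, reference_offset) entry per
    alignment column; a gap on either side is None. ``cpg_read_bases`` gives,
    for each reference CpG in order, the read base aligned to the CpG
    cytosine (None if gapped or outside the aligned span).
    """

    read_id: str
    score: float
    aligned_pairs: tuple[tuple[int | None, int | None], ...]
    aligned_fraction: float
    primer_similarity: float
    conversion_efficiency: float | None
    cpg_read_bases: tuple[str | None, ...]

    def __post_init__(self) -> None:
        refs = [r for _, r in self.aligned_pairs if r is not None]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("reference offsets in aligned_pairs must strictly increase")


@dataclass
class QCReport:
    """Per-filter attrition. Reads are counted at the first filter they fail."""

    n_input: int = 0
    n_fail_length: int = 0
    n_fail_primer: int = 0
    n_fail_conversion: int = 0
    n_fail_alignment: int = 0
    n_fail_ambiguous_cpg: int = 0
    n_retained: int = 0
    mean_conversion_efficiency: float | None = None

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_fail_length
            + self.n_fail_primer
            + self.n_fail_conversion
            + self.n_fail_alignment
            + self.n_fail_ambiguous_cpg
        )
        if total != self.n_input:
            raise AssertionError(f"QC counts {total} != n_input {self.n_input}")

    def record_ambiguous_drops(self, n_dropped: int) -> None:
        """Move reads dropped for ambiguous CpG calls out of the retained count."""
        self.n_fail_ambiguous_cpg += n_dropped
        self.n_retained -= n_dropped
        self.check()

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _make_aligner(cfg: QCConfig) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                mat[a, b] = 0.0
            elif a == b or {a, b} <= {"Y", "C"} or {a, b} <= {"Y", "T"}:
                mat[a, b] = cfg.match_score
            else:
                mat[a, b] = cfg.mismatch_score
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    # reference (target) overhangs are free: gaps at the query's ends
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


def _converted_with_ambiguity(ref: AmpliconReference) -> str:
    conv = list(bisulfite_convert(ref.sequence))
    for off in ref.cpg_offsets:
        conv[off] = "Y"
    # unannotated CpGs are still C/T-ambiguous after conversion
    for i, base in enumerate(conv):
        if base == "C":
            conv[i] = "Y"
    return "".join(conv)


def _non_cpg_c_offsets(ref: AmpliconReference) -> np.ndarray:
    seq = ref.sequence
    offs = [
        i
        for i, b in enumerate(seq)
        if b == "C" and (i == len(seq) - 1 or seq[i + 1] != "G")
    ]
    return np.asarray(offs, dtype=int)


def align_read(read: ReadRecord, ref: AmpliconReference, config: QCConfig | None = None) -> Alignment:
    """Semi-global alignment of one read against the converted reference.

    Raises :class:`NonAmpliconError` for reads longer than 3x the reference.
    Deterministic given inputs and scoring configuration (the first optimal
    traceback is taken).
    """
    cfg = config or QCConfig()
    if len(read.sequence) > 3 * len(ref.sequence):
        raise NonAmpliconError(
            f"read {read.id!r} is {len(read.sequence)} nt, "
            f"over 3x the {len(ref.sequence)} nt reference"
        )
    target = _converted_with_ambiguity(ref)
    query = "".join(b if b in _ALPHABET else "N" for b in read.sequence)
    aligner = _make_aligner(cfg)
    aln = aligner.align(target, query)[0]

    pairs: list[tuple[int | None, int | None]] = []
    ref_to_read: dict[int, int | None] = {}
    coords = aln.coordinates  # rows: target, query
    for (t0, q0), (t1, q1) in zip(coords.T[:-1], coords.T[1:]):
        if t1 > t0 and q1 > q0:  # aligned block
            for dt in range(t1 - t0):
                pairs.append((q0 + dt, t0 + dt))
                ref_to_read[t0 + dt] = q0 + dt
        elif t1 > t0:  # gap in read
            for dt in range(t1 - t0):
                pairs.append((None, t0 + dt))
                ref_to_read[t0 + dt] = None
        else:  # gap in reference (read insertion)
            for dq in range(q1 - q0):
                pairs.append((q0 + dq, None))

    n_matched = sum(1 for q, t in pairs if q is not None and t is not None)
    aligned_fraction = n_matched / len(read.sequence)

    cpg_bases: list[str | None] = []
    for off in ref.cpg_offsets:
        q = ref_to_read.get(off)
        cpg_bases.append(read.sequence[q] if q is not None else None)

    covered = 0
    converted = 0
    for off in _non_cpg_c_offsets(ref):
        q = ref_to_read.get(int(off))
        if q is not None:
            covered += 1
            if read.sequence[q] == "T":
                converted += 1
    conv_eff = converted / covered if covered else None

    return Alignment(
        read_id=read.id,
        score=float(aln.score),
        aligned_pairs=tuple(pairs),
        aligned_fraction=aligned_fraction,
        primer_similarity=primer_similarity(read, ref),
        conversion_efficiency=conv_eff,
        cpg_read_bases=tuple(cpg_bases),
    )


def length_filter(read: ReadRecord, ref: AmpliconReference, min_frac: float = 0.5,
                  window: tuple[int, int] | None = None) -> bool:
    """Pass iff read length >= min_frac x reference length (and inside the
    optional absolute window)."""
    if window is not None and not (window[0] <= len(read.sequence) <= window[1]):
        return False
    return len(read.sequence) >= min_frac * len(ref.sequence)


def primer_similarity(read: ReadRecord, ref: AmpliconReference) -> float:
    """Best ungapped identity of the converted forward primer within the
    first 1.5x primer-length window of the read.

    CpG-context primer positions accept both C and T.
    """
    primer = bisulfite_convert(ref.forward_primer)
    ambig = {
        i
        for i in range(len(ref.forward_primer))
        if ref.forward_primer[i] == "C"
        and i + 1 < len(ref.forward_primer)
        and ref.forward_primer[i + 1] == "G"
    }
    L = len(primer)
    if L == 0:
        raise ValueError(f"{ref.name}: empty forward primer")
    if L > len(read.sequence):
        return 0.0
    limit = min(len(read.sequence) - L, int(1.5 * L) - L)
    best = 0.0
    for start in range(limit + 1):
        window = read.sequence[start : start + L]
        hits = sum(
            1
            for i, (p, b) in enumerate(zip(primer, window))
            if p == b or (i in ambig and b in "CT")
        )
        best = max(best, hits / L)
    return best


def primer_filter(read: ReadRecord, ref: AmpliconReference, min_sim: float = 0.80) -> bool:
    return primer_similarity(read, ref) >= min_sim


def conversion_filter(aln: Alignment, min_eff: float = 0.98) -> bool:
    """Pass iff the read's bisulfite conversion efficiency is >= min_eff.

    A read covering zero non-CpG-context cytosines is uninformative and fails.
    """
    if aln.conversion_efficiency is None:
        return False
    return aln.conversion_efficiency >= min_eff


def alignment_filter(aln: Alignment, min_frac: float = 0.60) -> bool:
    return aln.aligned_fraction >= min_frac


def run_qc(
    reads: Iterable[ReadRecord],
    ref: AmpliconReference,
    config: QCConfig | None = None,
) -> tuple[list[tuple[ReadRecord, Alignment]], QCReport]:
    """Apply the filter battery in order length -> primer -> conversion ->
    alignment, returning retained (read, alignment) pairs and the attrition
    report.

    Per-read alignment errors (non-amplicon reads) are counted as alignment
    failures; the batch never aborts.
    """
    cfg = config or QCConfig()
    report = QCReport()
    retained: list[tuple[ReadRecord, Alignment]] = []
    effs: list[float] = []
    for read in reads:
        report.n_input += 1
        if not length_filter(read, ref, cfg.min_length_frac, cfg.length_window):
            report.n_fail_length += 1
            continue
        if not primer_filter(read, ref, cfg.min_primer_sim):
            report.n_fail_primer += 1
            continue
        try:
            aln = align_read(read, ref, cfg)
        except NonAmpliconError:
            report.n_fail_alignment += 1
            continue
        if not conversion_filter(aln, cfg.min_conversion):
            report.n_fail_conversion += 1
            continue
        if not alignment_filter(aln, cfg.min_aligned_frac):
            report.n_fail_alignment += 1
            continue
        report.n_retained += 1
        if aln.conversion_efficiency is not None:
            effs.append(aln.conversion_efficiency)
        retained.append((read, aln))
    report.mean_conversion_efficiency = float(np.mean(effs)) if effs else None
    report.check()
    return retained, report
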