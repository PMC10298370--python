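"""Per-read methylation calls and epiallele tabulation.

An epiallele is a distinct binary methylation pattern over the CpGs of one
amplicon-length molecule: at each CpG the retained read shows C (methylated,
coded 1) or T (unmethylated, coded 0). Anything else at a CpG -- A, G, N, a
gap, or a CpG outside the aligned span -- is an ambiguous call, and reads
with any ambiguous call are dropped when the methylation matrix is built, so
every tabulated pattern has full length. A 6-CpG amplicon therefore has a
pattern space of 2^6 = 64 epialleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import AmpliconReference
from .read_qc import Alignment

__all__ = [
    "MethCallVector",
    "MethMatrix",
    "EpialleleTable",
    "call_methylation",
    "build_matrix",
    "tabulate",
]

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "?"


@dataclass(frozen=True)
class MethCallVector:
    """Per-CpG calls for one read, in reference CpG order."""

    read_id: str
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.calls) - {METHYLATED, UNMETHYLATED, AMBIGUOUS}
        if bad:
            raise ValueError(f"invalid call values {bad}")

    @property
    def is_complete(self) -> bool:
        return AMBIGUOUS not in self.calls


@dataclass
class MethMatrix:
    """Reads x CpGs binary methylation matrix (1=methylated, 0=unmethylated)."""

    sample_id: str
    cpg_labels: tuple[int, ...]
    data: np.ndarray  # shape (n_reads, n_cpgs), dtype uint8
    read_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.data.shape[1] != len(self.cpg_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.cpg_labels)} CpG labels"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("matrix values must be 0/1")
        if self.read_ids and len(self.read_ids) != self.data.shape[0]:
            raise ValueError("read_ids length != row count")

    @property
    def n_reads(self) -> int:
        return self.data.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.data.shape[1]


@dataclass
class EpialleleTable:
    """Counts of distinct methylation patterns in one sample.

    Patterns are fixed-length strings over {1, 0} aligned to ``cpg_labels``
    order, 1 = methylated.
    """

    sample_id: str
    cpg_labels: tuple[int, ...]
    counts: dict[str, int]
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.cpg_labels)
        for pat, c in self.counts.items():
            if len(pat) != k or set(pat) - {"0", "1"}:
                raise ValueError(f"bad pattern {pat!r} for {k} CpGs")
            if c <= 0:
                raise ValueError(f"non-positive count for pattern {pat!r}")
        self.n_total = sum(self.counts.values())

    @property
    def n_patterns(self) -> int:
        return len(self.counts)

    def frequencies(self) -> dict[str, float]:
        return {p: c / self.n_total for p, c in self.counts.items()}

    def pattern_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(patterns as 0/1 matrix, counts), rows sorted by pattern string."""
        pats = sorted(self.counts)
        mat = np.array([[int(b) for b in p] for p in pats], dtype=np.uint8)
        if not pats:
            mat = mat.reshape(0, len(self.cpg_labels))
        cnt = np.array([self.counts[p] for p in pats], dtype=np.int64)
        return mat, cnt

    def expand(self) -> MethMatrix:
        """Back to a read-level matrix (one row per molecule, pattern order)."""
        rows = [
            [int(b) for b in pat]
            for pat in sorted(self.counts)
            for _ in range(self.counts[pat])
        ]
        data = np.array(rows, dtype=np.uint8).reshape(-1, len(self.cpg_labels))
        return MethMatrix(self.sample_id, self.cpg_labels, data)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "pattern": list(sorted(self.counts)),
                "count": [self.counts[p] for p in sorted(self.counts)],
                "frequency": [self.counts[p] / self.n_total for p in sorted(self.counts)],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cpg_labels: Sequence[int],
                   sample_id: str | None = None) -> "EpialleleTable":
        if sample_id is not None:
            frame = frame[frame["sample"].astype(str) == str(sample_id)]
            sid = sample_id
        else:
            sids = frame["sample"].astype(str).unique()
            if len(sids) != 1:
                raise ValueError(f"frame holds {len(sids)} samples; pass sample_id")
            sid = sids[0]
        counts = {
            str(row.pattern).zfill(len(cpg_labels)): int(row.count)
            for row in frame.itertuples()
        }
        return cls(sample_id=str(sid), cpg_labels=tuple(cpg_labels), counts=counts)


def call_methylation(aln: Alignment, ref: AmpliconReference) -> MethCallVector:
    """Call M/U/ambiguous at each reference CpG from a retained alignment.

    C -> methylated, T -> unmethylated; A, G, N, a gap, or an uncovered CpG
    -> ambiguous. Ambiguity is a value, not an error; affected reads are
    removed at matrix build.
    """
    calls = []
    for base in aln.cpg_read_bases:
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    return MethCallVector(read_id=aln.read_id, calls=tuple(calls))


def build_matrix(
    calls: Iterable[MethCallVector],
    cpg_labels: Sequence[int],
    sample_id: str = "",
) -> tuple[MethMatrix, int]:
    """Assemble complete call vectors into a MethMatrix.

    Returns the matrix and the number of reads dropped for carrying at least
    one ambiguous CpG call (to be folded into the QC report).
    """
    rows = []
    ids = []
    n_dropped = 0
    for cv in calls:
        if len(cv.calls) != len(cpg_labels):
            raise ValueError(
                f"read {cv.read_id!r}: {len(cv.calls)} calls for {len(cpg_labels)} CpGs"
            )
        if cv.is_complete:
            rows.append([1 if c == METHYLATED else 0 for c in cv.calls])
            ids.append(cv.read_id)
        else:
            n_dropped += 1
    data = np.array(rows, dtype=np.uint8).reshape(-1, len(cpg_labels))
    return MethMatrix(sample_id, tuple(cpg_labels), data, tuple(ids)), n_dropped


def tabulate(matrix: MethMatrix) -> EpialleleTable:
    """Count distinct binary patterns (epialleles) in a methylation matrix."""
    if matrix.n_reads == 0:
        return EpialleleTable(matrix.sample_id, matrix.cpg_labels, {})
    pats, cnts = np.unique(matrix.data, axis=0, return_counts=True)
    counts = {
        "".join(str(int(b)) for b in row): int(c) for row, c in zip(pats, cnts)
    }
    return EpialleleTable(matrix.sample_id, matrix.cpg_labels, counts)
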