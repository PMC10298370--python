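"""Amplicon references, read I/O and tabular serialization.

An amplicon is defined on the genomic (pre-bisulfite) plus strand together
with its primer pair and a coordinate map for its CpGs: internal addressing
uses 0-based offsets of the CpG cytosine within the amplicon sequence, while
every user-facing output uses the integer TSS-relative labels under which the
CpGs are reported (e.g. DDO CpG 105). Minus-strand amplicons are separate
references with their own coordinate maps; no strand merging is attempted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconReference",
    "ReadRecord",
    "SampleManifest",
    "load_reads",
    "write_reads",
    "bisulfite_convert",
    "bisulfite_convert_reference",
    "write_table",
    "read_table",
    "load_references",
    "load_manifest",
]

_VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class AmpliconReference:
    """A targeted bisulfite amplicon with its CpG coordinate map.

    ``sequence`` is the genomic plus-strand sequence before bisulfite
    treatment. ``cpg_offsets[i]`` is the 0-based position of the C of the
    i-th CpG; ``cpg_labels[i]`` is its TSS-relative integer label.
    """

    name: str
    sequence: str
    forward_primer: str
    reverse_primer: str
    cpg_offsets: tuple[int, ...]
    cpg_labels: tuple[int, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "forward_primer", self.forward_primer.upper())
        object.__setattr__(self, "reverse_primer", self.reverse_primer.upper())
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        object.__setattr__(self, "cpg_labels", tuple(int(l) for l in self.cpg_labels))
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")
        if len(self.cpg_offsets) != len(self.cpg_labels):
            raise ValueError(
                f"{self.name}: {len(self.cpg_offsets)} offsets but {len(self.cpg_labels)} labels"
            )
        if len(set(self.cpg_labels)) != len(self.cpg_labels):
            raise ValueError(f"{self.name}: duplicate CpG labels")
        if any(b <= a for a, b in zip(self.cpg_offsets, self.cpg_offsets[1:])):
            raise ValueError(f"{self.name}: cpg_offsets must be strictly increasing")
        for off in self.cpg_offsets:
            if not (0 <= off < len(self.sequence) - 1):
                raise ValueError(f"{self.name}: CpG offset {off} out of range")
            if self.sequence[off : off + 2] != "CG":
                raise ValueError(
                    f"{self.name}: offset {off} is "
                    f"{self.sequence[off:off + 2]!r}, expected 'CG'"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def label_of(self, offset: int) -> int:
        return self.cpg_labels[self.cpg_offsets.index(offset)]


@dataclass
class ReadRecord:
    """One merged amplicon read (post paired-end merging)."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass
class SampleManifest:
    """One sample (one read file) within an ordered experimental design."""

    sample_id: str
    time_label: str
    read_file: str
    reference_name: str
    time_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.time_order and self.time_label not in self.time_order:
            raise ValueError(
                f"sample {self.sample_id}: time label {self.time_label!r} "
                f"not in declared order {self.time_order}"
            )


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot infer read format from {path!r}; pass format=")


def load_reads(path: str | Path, format: str | None = None) -> list[ReadRecord]:
    """Load merged reads from FASTA or FASTQ, preserving file order.

    A malformed record raises ``ValueError`` naming the 1-based record index
    at which parsing failed. An empty file yields an empty list.
    """
    fmt = _infer_format(path, format)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported read format {fmt!r}")
    records: list[ReadRecord] = []
    parser = SeqIO.parse(str(path), fmt)
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed {fmt} at record {len(records) + 1}: {exc}"
            ) from exc
        quals = rec.letter_annotations.get("phred_quality")
        records.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(quals) if quals is not None else None,
            )
        )
    return records


def write_reads(records: Iterable[ReadRecord], path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    seqrecords = []
    for r in records:
        sr = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            sr.letter_annotations["phred_quality"] = (
                r.qualities if r.qualities is not None else [40] * len(r.sequence)
            )
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), fmt)


def bisulfite_convert(sequence: str) -> str:
    """In-silico bisulfite conversion of a reference strand.

    Every C not followed by G becomes T (full conversion of non-CpG
    cytosines). CpG-context Cs are kept as C; downstream alignment treats
    those positions as C/T-ambiguous, since a CpG reads C when methylated
    and T when not. Idempotent.
    """
    return re.sub(r"C(?!G)", "T", sequence.upper())


def bisulfite_convert_reference(ref: AmpliconReference) -> str:
    """Bisulfite-converted reference sequence (CpG Cs retained as C)."""
    return bisulfite_convert(ref.sequence)


def write_table(frame: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a tabular result as TSV or JSON (records orientation).

    Floats are serialized at full round-trip precision so extreme p-values
    (1e-300) survive a write/read cycle in text.
    """
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        Path(path).write_text(
            json.dumps(frame.to_dict(orient="records"), indent=1, default=str) + "\n"
        )
    else:
        raise ValueError(f"unsupported table format {fmt!r}")


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt == "tsv":
        # binary pattern strings must not collapse to integers
        frame = pd.read_csv(path, sep="\t", dtype={"pattern": str, "core": str})
    elif fmt == "json":
        frame = pd.DataFrame(json.loads(Path(path).read_text()))
    else:
        raise ValueError(f"unsupported table format {fmt!r}")
    return frame


def load_references(path: str | Path) -> dict[str, AmpliconReference]:
    """Load amplicon references from a YAML config.

    Layout::

        amplicons:
          DDO:
            sequence: ACGT...
            forward_primer: ...
            reverse_primer: ...
            cpg_offsets: [12, 45, ...]
            cpg_labels: [105, 138, ...]
            strand: "+"
    """
    cfg = yaml.safe_load(Path(path).read_text())
    refs = {}
    for name, entry in cfg["amplicons"].items():
        refs[name] = AmpliconReference(
            name=name,
            sequence=entry["sequence"],
            forward_primer=entry["forward_primer"],
            reverse_primer=entry["reverse_primer"],
            cpg_offsets=tuple(entry["cpg_offsets"]),
            cpg_labels=tuple(entry["cpg_labels"]),
            strand=str(entry.get("strand", "+")),
        )
    return refs


def load_manifest(path: str | Path) -> list[SampleManifest]:
    """Load a sample manifest TSV (sample_id, time_label, read_file, reference_name).

    The declared time order is the order of first appearance of time labels.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_label", "read_file", "reference_name"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    order = tuple(dict.fromkeys(str(t) for t in frame["time_label"]))
    return [
        SampleManifest(
            sample_id=str(row.sample_id),
            time_label=str(row.time_label),
            read_file=str(row.read_file),
            reference_name=str(row.reference_name),
            time_order=order,
        )
        for row in frame.itertuples()
    ]
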