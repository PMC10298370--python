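import numpy as np
import pytest

from methcore import (
    AmpliconReference,
    EpialleleTable,
    ReadRecord,
    bisulfite_convert,
    make_reference,
)


@pytest.fixture(scope="session")
def toy_ref() -> AmpliconReference:
    """Tiny hand-auditable amplicon: 3 CpGs at offsets 2, 6, 11."""
    seq = "AACGTTCGATACGTA"
    return AmpliconReference(
        name="toy",
        sequence=seq,
        forward_primer=seq[:5],
        reverse_primer="TACGT",
        cpg_offsets=(2, 6, 11),
        cpg_labels=(10, 20, 30),
    )


@pytest.fixture(scope="session")
def ddo_ref() -> AmpliconReference:
    return make_reference("DDO", seed=1)


def table_from_counts(counts: dict[str, int], labels=None, sample="s") -> EpialleleTable:
    if labels is None:
        k = len(next(iter(counts)))
        labels = tuple(range(1, k + 1))
    return EpialleleTable(sample_id=sample, cpg_labels=tuple(labels), counts=counts)


def random_table(rng: np.random.Generator, n_cpgs: int, n_reads: int,
                 marginals=None, planted=None, prevalence=0.0) -> EpialleleTable:
    """Random epiallele table with independent CpGs, optionally a planted core.

    ``planted`` is a tuple of column indices jointly methylated (with
    fidelity 0.95) in a ``prevalence`` fraction of molecules.
    """
    if marginals is None:
        marginals = rng.uniform(0.05, 0.6, size=n_cpgs)
    probs = np.tile(np.asarray(marginals, dtype=float), (n_reads, 1))
    if planted:
        members = rng.random(n_reads) < prevalence
        probs[np.ix_(members, list(planted))] = 0.95
    data = (rng.random((n_reads, n_cpgs)) < probs).astype(np.uint8)
    pats, cnts = np.unique(data, axis=0, return_counts=True)
    counts = {"".join(str(b) for b in row): int(c) for row, c in zip(pats, cnts)}
    return EpialleleTable(
        sample_id="rand", cpg_labels=tuple(range(1, n_cpgs + 1)), counts=counts
    )


def perfect_read(ref: AmpliconReference, pattern: str | None = None,
                 read_id: str = "r") -> ReadRecord:
    """Fully converted, error-free read carrying the given methylation pattern
    (default: all methylated)."""
    conv = list(bisulfite_convert(ref.sequence))
    bits = pattern or "1" * ref.n_cpgs
    for off, bit in zip(ref.cpg_offsets, bits):
        conv[off] = "C" if bit == "1" else "T"
    return ReadRecord(id=read_id, sequence="".join(conv))


def qc_violation_reads(ref: AmpliconReference) -> tuple[list[ReadRecord], dict]:
    """8-read fixture: three perfect reads plus one violator per QC filter
    and one read with an ambiguous CpG call.

    Returns the reads and the intended per-filter failure counts.
    """
    rng = np.random.default_rng(42)
    good = [perfect_read(ref, read_id=f"good{i}") for i in range(3)]
    conv = bisulfite_convert(ref.sequence)

    short = ReadRecord("fail_length", conv[: int(0.4 * len(conv))])

    # scramble the primer region beyond 20% dissimilarity
    bad_primer_seq = list(conv)
    plen = len(ref.forward_primer)
    for i in range(0, plen, 2):
        bad_primer_seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad_primer_seq[i]]
    bad_primer = ReadRecord("fail_primer", "".join(bad_primer_seq))

    # revert enough non-CpG Ts (outside the primer) back to C to sink
    # conversion efficiency below 98%
    seq = ref.sequence
    non_cpg_c = [i for i, b in enumerate(seq)
                 if b == "C" and (i == len(seq) - 1 or seq[i + 1] != "G")]
    plen = len(ref.forward_primer)
    revert = [i for i in non_cpg_c if i >= plen][: max(2, len(non_cpg_c) // 10)]
    bad_conv_seq = list(conv)
    for i in revert:
        bad_conv_seq[i] = "C"
    bad_conv = ReadRecord("fail_conversion", "".join(bad_conv_seq))

    # perfect amplicon plus a long unalignable tail: the tail bases stay
    # unpaired, so aligned fraction ~ 1/1.8 < 0.6 while the aligned span is
    # perfectly converted
    bad_aln = ReadRecord("fail_alignment", conv + "A" * int(0.8 * len(conv)))

    amb_seq = list(conv)
    amb_seq[ref.cpg_offsets[1]] = "N"
    ambiguous = ReadRecord("fail_ambiguous", "".join(amb_seq))

    reads = good + [short, bad_primer, bad_conv, bad_aln, ambiguous]
    expected = dict(n_fail_length=1, n_fail_primer=1, n_fail_conversion=1,
                    n_fail_alignment=1, n_fail_ambiguous_cpg=1, n_retained=3)
    return reads, expected
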