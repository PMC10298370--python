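"""Population-level statistics over epiallele tables.

Covers the descriptive layer of the analysis: per-CpG and per-sample average
methylation, Shannon entropy of the epiallele distribution (heterogeneity of
the molecule population, in bits), unpaired two-group comparison of average
methylation, Pearson correlation between stage-wise epiallele distributions,
and PCA of epiallele abundance across samples.

Entropy is reported in bits (log base 2). Because the maximum attainable
entropy depends on both the pattern-space size 2^k and the read depth n, a
normalized value H / log2(min(n, 2^k)) is emitted alongside the raw one so
samples of different depth can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .epiallele import EpialleleTable

__all__ = [
    "MethylationProfile",
    "mean_methylation",
    "shannon_entropy",
    "normalized_entropy",
    "methylation_profile",
    "compare_two_groups",
    "stage_correlation",
    "epiallele_pca",
    "PCAResult",
]


@dataclass(frozen=True)
class MethylationProfile:
    """Summary statistics of one sample's methylation population."""

    sample_id: str
    per_cpg_mean: dict[int, float]
    overall_mean: float
    entropy_bits: float
    entropy_normalized: float
    n_reads: int


def _check_nonempty(table: EpialleleTable) -> None:
    if table.n_total == 0:
        raise ValueError(f"sample {table.sample_id!r}: no retained reads")


def mean_methylation(table: EpialleleTable) -> tuple[dict[int, float], float]:
    """Per-CpG methylation fractions and their unweighted mean.

    The per-CpG fraction is sum(count * pattern_bit) / n_total.
    """
    _check_nonempty(table)
    pats, cnts = table.pattern_array()
    col = (pats * cnts[:, None]).sum(axis=0) / table.n_total
    per_cpg = {lab: float(f) for lab, f in zip(table.cpg_labels, col)}
    return per_cpg, float(col.mean())


def shannon_entropy(table: EpialleleTable) -> float:
    """Shannon entropy (bits) of the epiallele frequency distribution.

    H = -sum p_i log2 p_i with 0 log 0 := 0. Zero iff the sample is a single
    epiallele; at most k bits for a k-CpG amplicon.
    """
    _check_nonempty(table)
    _, cnts = table.pattern_array()
    p = cnts / cnts.sum()
    return float(stats.entropy(p, base=2))


def normalized_entropy(table: EpialleleTable) -> float:
    """Entropy divided by log2(min(n_total, 2^k)): depth-comparable in [0,1]."""
    h = shannon_entropy(table)
    k = len(table.cpg_labels)
    hmax = np.log2(min(table.n_total, 2 ** k))
    return float(h / hmax) if hmax > 0 else 0.0


def methylation_profile(table: EpialleleTable) -> MethylationProfile:
    per_cpg, overall = mean_methylation(table)
    return MethylationProfile(
        sample_id=table.sample_id,
        per_cpg_mean=per_cpg,
        overall_mean=overall,
        entropy_bits=shannon_entropy(table),
        entropy_normalized=normalized_entropy(table),
        n_reads=table.n_total,
    )


def compare_two_groups(means_a: Sequence[float], means_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unpaired Student t-test on replicate average-methylation values."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def stage_correlation(table_a: EpialleleTable, table_b: EpialleleTable) -> float:
    """Pearson correlation between two epiallele frequency distributions.

    Computed over the union of the two pattern spaces, with patterns absent
    from one sample counted as frequency 0.
    """
    _check_nonempty(table_a)
    _check_nonempty(table_b)
    if table_a.cpg_labels != table_b.cpg_labels:
        raise ValueError("tables are on different CpG label sets")
    union = sorted(set(table_a.counts) | set(table_b.counts))
    fa = np.array([table_a.counts.get(p, 0) / table_a.n_total for p in union])
    fb = np.array([table_b.counts.get(p, 0) / table_b.n_total for p in union])
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        raise ValueError("degenerate distribution: zero variance over the union space")
    r, _ = stats.pearsonr(fa, fb)
    return float(r)


@dataclass(frozen=True)
class PCAResult:
    sample_ids: tuple[str, ...]
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # samples x components
    pattern_space: tuple[str, ...]


def epiallele_pca(tables: Sequence[EpialleleTable], n_components: int | None = None) -> PCAResult:
    """PCA of epiallele abundance across samples.

    Rows are samples, columns the union pattern space; frequencies (not raw
    counts) are used so read depth does not drive the components. Components
    are those of the column-centered frequency matrix; variance-explained
    fractions are non-increasing and sum to at most 1.
    """
    if len(tables) < 2:
        raise ValueError("PCA needs at least 2 samples")
    labels = tables[0].cpg_labels
    if any(t.cpg_labels != labels for t in tables):
        raise ValueError("tables are on different CpG label sets")
    union = sorted(set().union(*(t.counts for t in tables)))
    X = np.array(
        [[t.counts.get(p, 0) / t.n_total for p in union] for t in tables], dtype=float
    )
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, *X.shape), svd_solver="full")
    with np.errstate(invalid="ignore", divide="ignore"):  # all-identical samples
        scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if pca.explained_variance_.sum() < 1e-15:  # identical samples
        ratios = np.zeros_like(ratios)
    return PCAResult(
        sample_ids=tuple(t.sample_id for t in tables),
        explained_variance_ratio=ratios,
        scores=scores,
        pattern_space=tuple(union),
    )


def profiles_frame(tables: Sequence[EpialleleTable]) -> pd.DataFrame:
    """Long-format summary table (one row per sample) for serialization."""
    rows = []
    for t in tables:
        prof = methylation_profile(t)
        row: dict = {
            "sample": prof.sample_id,
            "n_reads": prof.n_reads,
            "mean_methylation": prof.overall_mean,
            "entropy_bits": prof.entropy_bits,
            "entropy_normalized": prof.entropy_normalized,
        }
        for lab, frac in prof.per_cpg_mean.items():
            row[f"cpg_{lab}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
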