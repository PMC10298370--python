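"""Detection and tracking of stable methylation cores.

A methylation core is a set of >= 2 (possibly non-contiguous) CpGs that are
jointly methylated in a larger fraction of molecules than CpG-wise
independence would produce. The molecule population of a locus is typically
heterogeneous -- individual epialleles are rare -- yet a subset of CpGs can
be co-methylated in a substantial, stable fraction of molecules, marking an
epiallele family descended from a common ancestor. This module makes that
notion statistically explicit.

Null model. Under the null, CpGs methylate independently with probabilities
equal to their observed marginal frequencies m_j / n. The observed joint
count k_obs (molecules methylated at every member CpG) is scored by its
upper tail under this null. Two computations are available:

* ``binomial`` -- plug-in approximation: X ~ Binomial(n, p0) with
  p0 = prod(m_j / n). Fast, and conservative in the far upper tail (the
  regime where cores are called at alpha = 1e-10), because treating the
  margins as probabilities rather than conditioning on them over-disperses
  the null.
* ``conditional`` -- the exact distribution of the intersection size of
  independent uniformly random m_j-subsets of n molecules, i.e. the null
  obtained by independently permuting each CpG column. Computed by iterated
  hypergeometric convolution; this is the distribution a Monte-Carlo column
  permutation samples, so the two agree to MC accuracy.

A core is reported as significant when p < alpha (default 1e-10), the
observed joint frequency exceeds its independence expectation, and the joint
frequency reaches a prevalence floor (default 0.25 of molecules; 0.5 is the
stricter "majority" preset).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epiallele import EpialleleTable

__all__ = [
    "Core",
    "CoreTrajectory",
    "CoreConfig",
    "joint_frequency",
    "core_pvalue",
    "core_pvalue_conditional",
    "enumerate_cores",
    "maximal_cores",
    "track_cores",
    "cores_frame",
    "trajectories_frame",
]

logger = logging.getLogger(__name__)

LOW_DEPTH_READS = 50


@dataclass(frozen=True)
class CoreConfig:
    """Detection parameters.

    alpha: significance level on the core p-value (1e-10 by default).
    min_prevalence: joint-frequency floor for a reportable core; 0.25
        ("a relevant fraction of molecules") by default, 0.5 ("the majority")
        as a stricter documented preset.
    max_size: largest core size enumerated (6 by default, the largest core
        the method is expected to report on these amplicon designs).
    bonferroni: if True, p-values are multiplied by the number of subsets of
        size 2..max_size before the alpha comparison.
    pvalue_method: "binomial" (fast plug-in) or "conditional" (exact
        margin-conditioned null).
    """

    alpha: float = 1e-10
    min_prevalence: float = 0.25
    max_size: int = 6
    bonferroni: bool = False
    pvalue_method: str = "binomial"


@dataclass(frozen=True)
class Core:
    """A candidate or significant methylation core in one sample."""

    cpg_labels: tuple[int, ...]
    f_obs: float
    f_exp: float
    p_value: float
    n_reads: int
    significant: bool
    low_depth: bool = False

    @property
    def size(self) -> int:
        return len(self.cpg_labels)

    @property
    def label_str(self) -> str:
        return "-".join(str(l) for l in self.cpg_labels)


@dataclass
class CoreTrajectory:
    """One core's frequency and significance across ordered time points.

    ``frequencies[i]`` is the joint methylation frequency of the label set
    at ``time_labels[i]`` whether or not the core is significant there;
    ``stable`` is True iff the set is significant at >= 2 consecutive times.
    Trajectories whose label sets are related by inclusion (e.g. 105-138
    inside 105-138-150) share a ``lineage_id``.
    """

    cpg_labels: tuple[int, ...]
    time_labels: tuple[str, ...]
    frequencies: tuple[float, ...]
    significant: tuple[bool, ...]
    cores: dict[str, Core | None]
    stable: bool
    lineage_id: int

    @property
    def label_str(self) -> str:
        return "-".join(str(l) for l in self.cpg_labels)


def _table_arrays(table: EpialleleTable) -> tuple[np.ndarray, np.ndarray]:
    pats, cnts = table.pattern_array()
    return pats.astype(bool), cnts


def _label_indices(table: EpialleleTable, labels: Iterable[int]) -> list[int]:
    idx = []
    for lab in labels:
        if lab not in table.cpg_labels:
            raise ValueError(f"unknown CpG label {lab} for sample {table.sample_id!r}")
        idx.append(table.cpg_labels.index(lab))
    return idx


def joint_frequency(table: EpialleleTable, labels: Iterable[int]) -> float:
    """Fraction of molecules methylated at every CpG in ``labels``.

    Monotone non-increasing as labels are added.
    """
    if table.n_total == 0:
        raise ValueError("empty table")
    idx = _label_indices(table, labels)
    pats, cnts = _table_arrays(table)
    hit = pats[:, idx].all(axis=1)
    return float(cnts[hit].sum() / table.n_total)


def core_pvalue(n: int, k_obs: int, p0: float) -> float:
    """Upper-tail binomial p-value P(X >= k_obs | X ~ Bin(n, p0)).

    Computed through the regularized incomplete beta survival function,
    which stays accurate in log space far into the tail (p-values of 1e-300
    are resolved, not flushed to 0 prematurely).
    """
    if not 0 <= k_obs <= n:
        raise ValueError(f"k_obs {k_obs} outside [0, {n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 {p0} outside [0, 1]")
    if k_obs == 0:
        return 1.0
    return float(stats.binom.sf(k_obs - 1, n, p0))


def core_pvalue_conditional(n: int, k_obs: int, margins: Sequence[int]) -> float:
    """Exact margin-conditioned p-value P(K >= k_obs) under column permutation.

    K is the size of the intersection of independent uniformly random
    m_j-subsets of n molecules (m_j = observed per-CpG methylated counts).
    The distribution is built by iterated hypergeometric mixing:
    K after one column is m_1; conditional on K = s, adding a column with
    margin m gives K' ~ Hypergeometric(n, s, m).
    """
    margins = [int(m) for m in margins]
    if len(margins) < 1:
        raise ValueError("need at least one margin")
    if any(not 0 <= m <= n for m in margins):
        raise ValueError("margins must lie in [0, n]")
    if not 0 <= k_obs <= n:
        raise ValueError(f"k_obs {k_obs} outside [0, {n}]")
    if k_obs == 0:
        return 1.0
    dist = np.zeros(margins[0] + 1)
    dist[margins[0]] = 1.0
    for m in margins[1:]:
        s = np.nonzero(dist > 0)[0]
        hi = min(int(s.max(initial=0)), m)
        t = np.arange(hi + 1)
        # transition matrix: P(K'=t | K=s) for s rows, t columns
        trans = stats.hypergeom.pmf(t[None, :], n, s[:, None], m)
        new = dist[s] @ trans
        dist = np.zeros(hi + 1)
        dist[: hi + 1] = new
    if k_obs >= len(dist):
        return 0.0
    return float(min(1.0, dist[k_obs:].sum()))


def _subset_count(pats: np.ndarray, cnts: np.ndarray, idx: tuple[int, ...]) -> int:
    return int(cnts[pats[:, idx].all(axis=1)].sum())


def enumerate_cores(table: EpialleleTable, config: CoreConfig | None = None) -> list[Core]:
    """Enumerate all significant cores of size 2..max_size.

    Depth-first over CpG index subsets with prevalence pruning: joint
    frequency is monotone non-increasing in subset size, so a subset below
    the prevalence floor cannot be extended into a reportable core and its
    supersets are skipped. The pruning therefore never removes a core that
    would have been reported.

    Output is sorted by (size descending, p ascending, label order).
    """
    cfg = config or CoreConfig()
    if table.n_total == 0:
        raise ValueError("empty table")
    k = len(table.cpg_labels)
    max_size = cfg.max_size
    if max_size > k:
        logger.warning("max_size %d clamped to %d CpGs", max_size, k)
        max_size = k
    low_depth = table.n_total < LOW_DEPTH_READS
    if low_depth:
        logger.warning(
            "sample %s: only %d reads (low depth)", table.sample_id, table.n_total
        )
    pats, cnts = _table_arrays(table)
    n = table.n_total
    margins = (pats * cnts[:, None]).sum(axis=0).astype(int)
    marg_f = margins / n
    n_tests = sum(math.comb(k, s) for s in range(2, max_size + 1))
    min_count = cfg.min_prevalence * n

    found: list[Core] = []

    def evaluate(idx: tuple[int, ...], count: int) -> None:
        f_obs = count / n
        f_exp = float(np.prod(marg_f[list(idx)]))
        if cfg.pvalue_method == "conditional":
            p = core_pvalue_conditional(n, count, [int(margins[i]) for i in idx])
        else:
            p = core_pvalue(n, count, f_exp)
        if cfg.bonferroni:
            p = min(1.0, p * n_tests)
        if p < cfg.alpha and f_obs > f_exp and f_obs >= cfg.min_prevalence:
            found.append(
                Core(
                    cpg_labels=tuple(table.cpg_labels[i] for i in idx),
                    f_obs=f_obs,
                    f_exp=f_exp,
                    p_value=p,
                    n_reads=n,
                    significant=True,
                    low_depth=low_depth,
                )
            )

    def extend(idx: tuple[int, ...], count: int) -> None:
        for j in range(idx[-1] + 1 if idx else 0, k):
            new = idx + (j,)
            c = _subset_count(pats, cnts, new)
            if c < min_count:  # supersets can only be rarer
                continue
            if len(new) >= 2:
                evaluate(new, c)
            if len(new) < max_size:
                extend(new, c)

    extend((), n)
    found.sort(key=lambda c: (-c.size, c.p_value, c.cpg_labels))
    return found


def maximal_cores(cores: Sequence[Core], f_tol: float = 0.05) -> list[Core]:
    """Collapse nested cores, keeping the largest.

    A significant core is dropped when it is a strict subset of another
    significant core whose joint frequency is within ``f_tol`` of (or above)
    its own -- the superset explains the subset's signal at essentially the
    same prevalence.
    """
    keep = []
    for a in cores:
        sa = set(a.cpg_labels)
        absorbed = any(
            set(b.cpg_labels) > sa and b.significant and b.f_obs >= a.f_obs - f_tol
            for b in cores
        )
        if not absorbed:
            keep.append(a)
    keep.sort(key=lambda c: (-c.size, c.p_value, c.cpg_labels))
    return keep


def _lineage_ids(label_sets: Sequence[tuple[int, ...]]) -> list[int]:
    # union-find over sets related by inclusion
    parent = list(range(len(label_sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(label_sets)), 2):
        a, b = set(label_sets[i]), set(label_sets[j])
        if a <= b or b <= a:
            parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    out = []
    for i in range(len(label_sets)):
        r = find(i)
        out.append(roots.setdefault(r, len(roots)))
    return out


def track_cores(
    cores_by_time: Mapping[str, Sequence[Core]],
    tables_by_time: Mapping[str, EpialleleTable],
    time_order: Sequence[str],
) -> list[CoreTrajectory]:
    """Track core composition and frequency across ordered time points.

    Cores are grouped by label-set identity; label sets related by inclusion
    (a core that gained or lost members between stages) are additionally
    linked into one lineage. The frequency series of every trajectory is the
    joint methylation frequency of its label set at every time point,
    including times where it is not significant.
    """
    order = tuple(time_order)
    for t in list(cores_by_time) + list(tables_by_time):
        if t not in order:
            raise ValueError(f"unknown time label {t!r} (declared order: {order})")
    for t in order:
        if t not in tables_by_time:
            raise ValueError(f"no epiallele table for time {t!r}")

    label_sets: list[tuple[int, ...]] = []
    for t in order:
        for c in cores_by_time.get(t, ()):
            if c.significant and c.cpg_labels not in label_sets:
                label_sets.append(c.cpg_labels)
    label_sets.sort(key=lambda s: (-len(s), s))
    lineages = _lineage_ids(label_sets)

    trajectories = []
    for labels, lin in zip(label_sets, lineages):
        per_time_core: dict[str, Core | None] = {}
        sig = []
        freqs = []
        for t in order:
            match = next(
                (c for c in cores_by_time.get(t, ()) if c.cpg_labels == labels), None
            )
            per_time_core[t] = match
            sig.append(match is not None and match.significant)
            freqs.append(joint_frequency(tables_by_time[t], labels))
        stable = any(a and b for a, b in zip(sig, sig[1:]))
        trajectories.append(
            CoreTrajectory(
                cpg_labels=labels,
                time_labels=order,
                frequencies=tuple(freqs),
                significant=tuple(sig),
                cores=per_time_core,
                stable=stable,
                lineage_id=lin,
            )
        )
    return trajectories


def cores_frame(cores: Sequence[Core], sample_id: str = "") -> pd.DataFrame:
    cols = ["sample", "core", "size", "f_obs", "f_exp", "p_value", "n_reads",
            "significant", "low_depth"]
    rows = [
        {
            "sample": sample_id,
            "core": c.label_str,
            "size": c.size,
            "f_obs": c.f_obs,
            "f_exp": c.f_exp,
            "p_value": c.p_value,
            "n_reads": c.n_reads,
            "significant": c.significant,
            "low_depth": c.low_depth,
        }
        for c in cores
    ]
    return pd.DataFrame(rows, columns=cols)


def trajectories_frame(trajectories: Sequence[CoreTrajectory]) -> pd.DataFrame:
    cols = ["core", "lineage", "stable", "time", "frequency", "significant"]
    rows = [
        {
            "core": tr.label_str,
            "lineage": tr.lineage_id,
            "stable": tr.stable,
            "time": t,
            "frequency": f,
            "significant": s,
        }
        for tr in trajectories
        for t, f, s in zip(tr.time_labels, tr.frequencies, tr.significant)
    ]
    return pd.DataFrame(rows, columns=cols)
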