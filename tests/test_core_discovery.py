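import itertools
import math

import numpy as np
import pytest
from scipy import stats

from methcore import (
    Core,
    CoreConfig,
    core_pvalue,
    core_pvalue_conditional,
    enumerate_cores,
    joint_frequency,
    maximal_cores,
    track_cores,
)

from conftest import random_table, table_from_counts


class TestJointFrequency:
    def test_single_label_equals_marginal(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, 5, 150)
        pats, cnts = table.pattern_array()
        marg = (pats * cnts[:, None]).sum(axis=0) / table.n_total
        for i, lab in enumerate(table.cpg_labels):
            assert joint_frequency(table, [lab]) == pytest.approx(marg[i])

    def test_fully_methylated_table(self):
        table = table_from_counts({"1111": 70})
        assert joint_frequency(table, [1, 3, 4]) == 1.0

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, 6, 100)
        labels = [2, 4, 5]
        idx = [table.cpg_labels.index(l) for l in labels]
        hits = sum(
            c for p, c in table.counts.items() if all(p[i] == "1" for i in idx)
        )
        assert joint_frequency(table, labels) == pytest.approx(hits / table.n_total)

    def test_unknown_label_errors(self):
        table = table_from_counts({"11": 10})
        with pytest.raises(ValueError, match="unknown CpG label"):
            joint_frequency(table, [99])

    def test_monotone_under_label_addition(self):
        """joint_frequency(T) <= joint_frequency(S) whenever S is inside T."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = random_table(rng, 6, 80)
            labels = list(table.cpg_labels)
            size = int(rng.integers(2, 6))
            t_set = list(rng.choice(labels, size=size, replace=False))
            s_set = t_set[: size - 1]
            assert joint_frequency(table, t_set) <= joint_frequency(table, s_set) + 1e-12


class TestCorePvalue:
    def test_p0_one_gives_one(self):
        assert core_pvalue(100, 60, 1.0) == 1.0

    def test_zero_observed_gives_one(self):
        assert core_pvalue(100, 0, 0.3) == 1.0

    def test_matches_direct_binomial_summation(self):
        n, k_obs, p0 = 10, 9, 0.25
        oracle = sum(
            math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(k_obs, n + 1)
        )
        assert core_pvalue(n, k_obs, p0) == pytest.approx(oracle, rel=1e-12)

    def test_far_tail_resolved_without_premature_underflow(self):
        p = core_pvalue(5000, 1000, 0.05)
        assert 0 < p < 1e-300

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            core_pvalue(10, 11, 0.5)
        with pytest.raises(ValueError):
            core_pvalue(10, 5, 1.5)


class TestConditionalPvalue:
    def test_two_columns_is_hypergeometric(self):
        """With two CpGs the margin-conditioned null is the overlap of two
        random subsets, i.e. hypergeometric."""
        n, m1, m2 = 100, 49, 50
        for k_obs in (10, 25, 27, 35):
            oracle = float(stats.hypergeom.sf(k_obs - 1, n, m1, m2))
            assert core_pvalue_conditional(n, k_obs, [m1, m2]) == pytest.approx(oracle)

    def test_three_columns_matches_permutation_mc(self):
        rng = np.random.default_rng(7)
        n, margins, k_obs = 60, [30, 25, 40], 12
        B = 200_000
        hits = np.ones((B, n), dtype=bool)
        for m in margins:
            col = np.zeros(n, dtype=bool)
            col[:m] = True
            hits &= rng.permuted(np.tile(col, (B, 1)), axis=1)
        phat = float((hits.sum(axis=1) >= k_obs).mean())
        p = core_pvalue_conditional(n, k_obs, margins)
        se = np.sqrt(phat * (1 - phat) / B)
        assert abs(p - phat) < 4 * se

    def test_margin_order_invariant(self):
        p1 = core_pvalue_conditional(200, 30, [80, 120, 50])
        p2 = core_pvalue_conditional(200, 30, [50, 80, 120])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_binomial_dominates_in_far_upper_tail(self):
        """The plug-in binomial null is over-dispersed relative to the
        margin-conditioned null, so it is conservative where cores are called."""
        n, margins = 500, [200, 180, 220]
        p0 = np.prod(np.array(margins) / n)
        for k_obs in (80, 100, 120):
            assert core_pvalue(n, k_obs, float(p0)) >= core_pvalue_conditional(
                n, k_obs, margins
            )


def exhaustive_cores(table, cfg: CoreConfig):
    """All-subset evaluation oracle (no pruning), mirroring the contract."""
    pats, cnts = table.pattern_array()
    pats = pats.astype(bool)
    n = table.n_total
    margins = (pats * cnts[:, None]).sum(axis=0)
    k = len(table.cpg_labels)
    n_tests = sum(math.comb(k, s) for s in range(2, min(cfg.max_size, k) + 1))
    out = []
    for size in range(2, min(cfg.max_size, k) + 1):
        for idx in itertools.combinations(range(k), size):
            count = int(cnts[pats[:, idx].all(axis=1)].sum())
            f_obs = count / n
            f_exp = float(np.prod(margins[list(idx)] / n))
            p = core_pvalue(n, count, f_exp)
            if cfg.bonferroni:
                p = min(1.0, p * n_tests)
            if p < cfg.alpha and f_obs > f_exp and f_obs >= cfg.min_prevalence:
                out.append((tuple(table.cpg_labels[i] for i in idx), f_obs, p))
    return sorted(out, key=lambda t: (-len(t[0]), t[2], t[0]))


class TestEnumerateCores:
    def test_all_unmethylated_no_cores(self):
        table = table_from_counts({"000000": 500})
        assert enumerate_cores(table) == []

    def test_all_methylated_no_enrichment(self):
        """Saturated methylation has f_exp = 1: nothing beats independence."""
        table = table_from_counts({"111111": 500})
        assert enumerate_cores(table) == []

    def test_recovers_planted_core(self):
        rng = np.random.default_rng(10)
        table = random_table(
            rng, 6, 5000, marginals=[0.1] * 6, planted=(0, 1, 2), prevalence=0.6
        )
        cores = enumerate_cores(table)
        maximal = maximal_cores(cores)
        assert maximal[0].cpg_labels == (1, 2, 3)
        assert maximal[0].p_value < 1e-10

    def test_agrees_with_exhaustive_oracle(self):
        """Pruned DFS equals all-subset evaluation on small random tables."""
        rng = np.random.default_rng(11)
        cfg = CoreConfig(alpha=1e-6, min_prevalence=0.2, max_size=8)
        for trial in range(10):
            k = int(rng.integers(4, 9))
            planted = tuple(rng.choice(k, size=3, replace=False)) if trial % 2 else None
            table = random_table(rng, k, 400, planted=planted, prevalence=0.5)
            got = [(c.cpg_labels, c.f_obs, c.p_value) for c in enumerate_cores(table, cfg)]
            expected = exhaustive_cores(table, cfg)
            assert [g[0] for g in got] == [e[0] for e in expected]
            for g, e in zip(got, expected):
                assert g[1] == pytest.approx(e[1])
                assert g[2] == pytest.approx(e[2], rel=1e-9)

    def test_max_size_clamped(self, caplog):
        table = table_from_counts({"11": 60, "00": 40})
        cfg = CoreConfig(max_size=10, alpha=0.1)
        cores = enumerate_cores(table, cfg)  # must not raise
        assert all(c.size <= 2 for c in cores)

    def test_low_depth_flagged(self):
        table = table_from_counts({"11": 20, "00": 10})
        cores = enumerate_cores(table, CoreConfig(alpha=0.5))
        assert all(c.low_depth for c in cores)

    def test_bonferroni_only_raises_pvalues(self):
        rng = np.random.default_rng(12)
        table = random_table(rng, 5, 800, planted=(0, 1), prevalence=0.6)
        plain = {c.cpg_labels: c.p_value for c in enumerate_cores(table)}
        adj = {
            c.cpg_labels: c.p_value
            for c in enumerate_cores(table, CoreConfig(bonferroni=True))
        }
        for labels, p in adj.items():
            assert p >= plain[labels]
        assert set(adj) <= set(plain)


class TestMaximalCores:
    @staticmethod
    def _core(labels, f_obs):
        return Core(
            cpg_labels=tuple(labels), f_obs=f_obs, f_exp=0.01, p_value=1e-20,
            n_reads=1000, significant=True,
        )

    def test_nested_core_absorbed_within_tolerance(self):
        sub = self._core((105, 138), 0.60)
        sup = self._core((105, 138, 150), 0.58)
        assert maximal_cores([sub, sup]) == [sup]

    def test_nested_core_kept_when_superset_much_rarer(self):
        sub = self._core((105, 138), 0.60)
        sup = self._core((105, 138, 150), 0.40)
        kept = maximal_cores([sub, sup])
        assert sub in kept and sup in kept

    def test_disjoint_cores_kept(self):
        a, b = self._core((105, 138), 0.5), self._core((226, 293), 0.4)
        assert set(c.cpg_labels for c in maximal_cores([a, b])) == {
            (105, 138), (226, 293)
        }

    def test_empty_input(self):
        assert maximal_cores([]) == []


class TestTrackCores:
    TIMES = ("T0", "T2", "T4", "T8", "T14")

    def _table(self, freq):
        n = 1000
        k_on = int(freq * n)
        return table_from_counts(
            {"111": k_on, "000": n - k_on}, labels=(105, 138, 150)
        )

    def _core(self, labels, f):
        return Core(
            cpg_labels=labels, f_obs=f, f_exp=0.001, p_value=1e-30,
            n_reads=1000, significant=True,
        )

    def test_core_significant_at_all_times_is_stable(self):
        labels = (105, 138, 150)
        tables = {t: self._table(0.5) for t in self.TIMES}
        cores = {t: [self._core(labels, 0.5)] for t in self.TIMES}
        (traj,) = track_cores(cores, tables, self.TIMES)
        assert traj.stable is True
        assert traj.time_labels == self.TIMES
        assert all(f == pytest.approx(0.5) for f in traj.frequencies)

    def test_single_time_significance_not_stable(self):
        labels = (105, 138, 150)
        tables = {t: self._table(0.3) for t in self.TIMES}
        cores = {t: [] for t in self.TIMES}
        cores["T4"] = [self._core(labels, 0.3)]
        (traj,) = track_cores(cores, tables, self.TIMES)
        assert traj.stable is False
        assert traj.significant == (False, False, True, False, False)

    def test_subset_related_cores_share_lineage(self):
        """The DDO-style composition change 105-138-150 -> 105-138 is one lineage."""
        tables = {t: self._table(0.4) for t in self.TIMES}
        cores = {t: [] for t in self.TIMES}
        cores["T0"] = [self._core((105, 138, 150), 0.4)]
        cores["T8"] = [self._core((105, 138), 0.42)]
        trajs = track_cores(cores, tables, self.TIMES)
        assert len(trajs) == 2
        assert trajs[0].lineage_id == trajs[1].lineage_id

    def test_unknown_time_label_errors(self):
        tables = {"T0": self._table(0.4), "T99": self._table(0.4)}
        with pytest.raises(ValueError, match="unknown time"):
            track_cores({}, tables, self.TIMES)

    def test_frequency_series_covers_nonsignificant_times(self):
        labels = (105, 138, 150)
        tables = {t: self._table(f) for t, f in zip(self.TIMES, (0.1, 0.2, 0.6, 0.2, 0.1))}
        cores = {t: [] for t in self.TIMES}
        cores["T4"] = [self._core(labels, 0.6)]
        (traj,) = track_cores(cores, tables, self.TIMES)
        assert traj.frequencies == pytest.approx((0.1, 0.2, 0.6, 0.2, 0.1))


class TestNullCalibration:
    def test_no_false_cores_on_independent_cpgs(self):
        """Independent CpGs at alpha 1e-10: essentially no significant cores."""
        rng = np.random.default_rng(13)
        total = 0
        for _ in range(50):
            table = random_table(rng, 6, 2000)
            total += len(enumerate_cores(table))
        assert total == 0
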