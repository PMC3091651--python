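"""Rank-statistics kernels against enumeration oracles and scipy."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from repliorg.errors import UndefinedCorrelationError
from repliorg.org_stats import (
    bin_confound_analysis,
    category_predicate,
    correlate_subset,
    expression_bins,
    mann_whitney,
    spearman,
    track_correlation_matrix,
)
from repliorg.window_tracks import WindowTrack

from conftest import make_gene


def brute_spearman_p(x, y):
    """Oracle: two-sided p from full enumeration of rank permutations."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        hits += abs(r) >= obs - 1e-12
        total += 1
    return hits / total


def brute_mw(a, b):
    """Oracle: U for group a and exact two-sided p over all assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    mu = n1 * len(b) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [i for i in range(len(pooled)) if i not in combo]
        u = sum(
            (pooled[i] > pooled[j]) + 0.5 * (pooled[i] == pooled[j])
            for i in combo
            for j in rest
        )
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return u_obs, hits / total


class TestSpearman:
    def test_monotone_pairs(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle(self, rng):
        for n in (4, 5, 6, 7):
            for _ in range(10):
                x = rng.permutation(n).astype(float)
                y = rng.permutation(n).astype(float)
                res = spearman(x, y)
                assert res.method == "spearman_exact"
                assert res.p_two_sided == pytest.approx(brute_spearman_p(x, y))

    def test_rho_matches_scipy(self, rng):
        for n in (8, 30, 200):
            x = rng.normal(size=n)
            y = x * 0.5 + rng.normal(size=n)
            res = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert res.statistic == pytest.approx(ref.statistic)
            if n > 10:
                assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_t_approximation_close_to_exact_at_n10(self, rng):
        worst = 0.0
        for _ in range(100):
            x = rng.random(10)
            y = rng.random(10)
            res = spearman(x, y)
            assert res.method == "spearman_exact"
            rho = res.statistic
            t = rho * math.sqrt(8 / (1 - rho * rho)) if abs(rho) < 1 else math.inf
            p_t = 2 * sps.t.sf(abs(t), df=8)
            worst = max(worst, abs(p_t - res.p_two_sided))
        assert worst <= 0.02

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y**3)
        assert warped.statistic == pytest.approx(base.statistic)
        assert warped.p_two_sided == pytest.approx(base.p_two_sided)

    def test_ties_fall_back_to_t_approximation(self):
        res = spearman([1, 1, 2, 3, 4], [5, 4, 3, 2, 1])
        assert res.method == "spearman_t_approx"
        ref = sps.spearmanr([1, 1, 2, 3, 4], [5, 4, 3, 2, 1])
        assert res.statistic == pytest.approx(ref.statistic)

    def test_null_p_values_uniform(self, rng):
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            rejections += spearman(x, y).p_two_sided < 0.05
        lo, hi = sps.binom.ppf([0.005, 0.995], n_sims, 0.05)
        assert lo <= rejections <= hi

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2, np.nan], [1, 2, 3])


class TestMannWhitney:
    def test_separated_groups(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_two_sided == pytest.approx(2 / 6)
        assert res.method == "mw_exact"

    def test_identical_multisets_give_central_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_one_vs_three(self):
        res = mann_whitney([1], [2, 3, 4])
        assert res.statistic == 0
        assert res.p_two_sided == pytest.approx(2 / 4)

    def test_exact_p_exhaustive_small_groups(self):
        """All tie-free 2v2 through 4v4 shapes against the enumeration oracle."""
        rng = np.random.default_rng(7)
        for n1 in (2, 3, 4):
            for n2 in (2, 3, 4):
                pooled = rng.permutation(100)[: n1 + n2].astype(float)
                a, b = pooled[:n1], pooled[n1:]
                res = mann_whitney(a, b)
                u_ref, p_ref = brute_mw(a, b)
                assert res.method == "mw_exact"
                assert res.statistic == pytest.approx(u_ref)
                assert res.p_two_sided == pytest.approx(p_ref)

    def test_exact_matches_scipy(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 12))
            pooled = rng.permutation(1000)[: n1 + n2].astype(float)
            res = mann_whitney(pooled[:n1], pooled[n1:])
            ref = sps.mannwhitneyu(
                pooled[:n1], pooled[n1:], alternative="two-sided", method="exact"
            )
            assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_normal_approximation_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            a = rng.integers(0, 12, size=int(rng.integers(9, 25))).astype(float)
            b = rng.integers(0, 12, size=int(rng.integers(9, 25))).astype(float)
            res = mann_whitney(a, b)
            ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert res.method == "mw_normal"
            assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestExpressionBins:
    def test_even_split(self):
        bins = expression_bins(np.arange(24), 12)
        assert np.bincount(bins).tolist() == [2] * 12

    def test_remainder_goes_to_early_bins(self):
        bins = expression_bins(np.arange(25), 12)
        sizes = np.bincount(bins)
        assert sizes.tolist() == [3] + [2] * 11

    def test_single_bin(self):
        assert (expression_bins([3.0, 1.0, 2.0], 1) == 0).all()

    def test_bins_ordered_by_expression(self, rng):
        expr = rng.normal(size=100)
        bins = expression_bins(expr, 12)
        order = np.argsort(expr, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            expression_bins([1.0, 2.0], 3)


class TestBinConfound:
    def test_single_category_gives_no_usable_bins(self):
        n = 24
        report = bin_confound_analysis(
            np.arange(n, dtype=float), np.ones(n, bool), np.arange(n, dtype=float),
            n_bins=4,
        )
        assert report.n_usable == 0
        assert report.n_significant_distance == 0

    def test_constructed_distance_shift_detected_in_every_bin(self, rng):
        # within every expression bin, core distances sit exactly 10 below
        # non-core; with 12 core + 12 non-core per bin the MW test must fire
        n_bins, per = 4, 12
        expr, core, dist = [], [], []
        for b in range(n_bins):
            expr += [float(b)] * (2 * per)
            core += [True] * per + [False] * per
            dist += list(100 + rng.random(per)) + list(110 + rng.random(per))
        report = bin_confound_analysis(
            np.array(expr), np.array(core), np.array(dist), n_bins=n_bins
        )
        assert report.n_usable == n_bins
        assert report.n_significant_distance == n_bins
        assert (report.rows.loc[report.rows.usable, "direction"] == "core_shorter").all()

    def test_random_labels_reject_at_alpha(self, rng):
        # under the null the per-bin distance test should fire at ~alpha
        hits = trials = 0
        for _ in range(200):
            n = 120
            expr = rng.normal(size=n)
            dist = rng.random(n) * 1000
            core = rng.random(n) < 0.4
            report = bin_confound_analysis(expr, core, dist, n_bins=3)
            usable = report.rows.usable
            trials += int(usable.sum())
            hits += int((usable & (report.rows.p_distance < 0.05)).sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], trials, 0.05)
        assert lo <= hits <= hi


class TestCorrelateSubset:
    def _genes(self, rng, n=20):
        genes = []
        for i in range(n):
            cats = ["protein_coding"] + (["txn_translation"] if i % 2 else [])
            genes.append(
                make_gene(f"g{i}", 10 * i, 10 * i + 5, categories=cats,
                          expression=float(rng.normal()))
            )
        return genes

    def test_all_pass_predicate_equals_plain_spearman(self, rng):
        genes = self._genes(rng)
        x = [g.start for g in genes]
        y = [g.expression for g in genes]
        res = correlate_subset(genes, lambda g: g.start, lambda g: g.expression)
        ref = spearman(x, y)
        assert res == ref

    def test_excluding_absent_category_changes_nothing(self, rng):
        genes = self._genes(rng)
        base = correlate_subset(genes, lambda g: g.start, lambda g: g.expression)
        res = correlate_subset(
            genes, lambda g: g.start, lambda g: g.expression,
            category_predicate(exclude=("transposon",)),
        )
        assert res == base

    def test_subset_equals_direct_recomputation(self, rng):
        genes = self._genes(rng)
        pred = category_predicate(exclude=("txn_translation",))
        res = correlate_subset(genes, lambda g: g.start, lambda g: g.expression, pred)
        kept = [g for g in genes if pred(g)]
        assert res.n == len(kept) == 10
        ref = spearman([g.start for g in kept], [g.expression for g in kept])
        assert res == ref

    def test_missing_values_drop_genes(self, rng):
        genes = self._genes(rng) + [make_gene("gx", 500, 510)]
        res = correlate_subset(genes, lambda g: g.start, lambda g: g.expression)
        assert res.n == 20


class TestTrackCorrelations:
    def _track(self, name, values):
        v = np.asarray(values, dtype=float)
        return WindowTrack(name, 10, np.arange(len(v)) * 10,
                           np.arange(len(v)) * 10 + 5, v)

    def test_monotone_transform_tracks_fully_correlated(self):
        base = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        tracks = {"a": self._track("a", base), "b": self._track("b", base**3)}
        out = track_correlation_matrix(tracks)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_matrix_matches_pairwise_spearman(self, rng):
        vals = {
            "d": np.arange(22, dtype=float),
            "e": -np.arange(22) + rng.normal(0, 3, 22),
            "c": rng.normal(size=22),
        }
        tracks = {k: self._track(k, v) for k, v in vals.items()}
        out = track_correlation_matrix(tracks).set_index(["feature_a", "feature_b"])
        assert len(out) == 3
        for (fa, fb), row in out.iterrows():
            ref = spearman(vals[fa], vals[fb])
            assert row["rho"] == pytest.approx(ref.statistic)
            assert row["p"] == pytest.approx(ref.p_two_sided)

    def test_missing_windows_dropped_pairwise(self, rng):
        a = np.arange(10, dtype=float)
        b = a * 2
        b[3] = np.nan
        tracks = {"a": self._track("a", a), "b": self._track("b", b)}
        out = track_correlation_matrix(tracks)
        assert out.loc[0, "n"] == 9
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_mismatched_window_sets_rejected(self):
        tracks = {"a": self._track("a", [1, 2, 3]), "b": self._track("b", [1, 2])}
        with pytest.raises(ValueError):
            track_correlation_matrix(tracks)
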