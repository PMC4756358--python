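from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ramanmap.bands import default_band_table
from ramanmap.chemometrics import (
    ChemometricsError,
    DegenerateVarianceError,
    annotate_loading,
    correlate_loadings,
    cumulative_evr,
    fit_pca,
    group_stats,
    kruskal_wallis_rank,
    orient_to,
    percentile,
    rank_components,
    subject_segregation,
    wilcoxon_rank_sum,
)
from ramanmap.synthetic import make_basis_spectra

from .conftest import gaussian, make_metadata


# ---------------------------------------------------------------------------
# independent oracles (hand formulas / full enumeration)
# ---------------------------------------------------------------------------

def midranks(values):
    """Midranks computed by hand via argsort and tie averaging."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_oracle(groups):
    """Kruskal-Wallis H with tie correction, straight from the definition."""
    allv = np.concatenate(groups)
    N = allv.size
    ranks = midranks(allv)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie


def wilcoxon_exact_oracle(a, b):
    """Two-sided exact p by full enumeration of rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    n1, N = a.size, pooled.size
    w_obs = ranks[:n1].sum()
    ws = np.array([sum(c) for c in combinations(ranks, n1)])
    n_total = ws.size
    p = 2.0 * min((ws <= w_obs + 1e-9).sum(), (ws >= w_obs - 1e-9).sum()) / n_total
    return min(1.0, p)


def compositions(n, parts):
    """All ways to split n items into `parts` ordered groups, each >= 1."""
    if parts == 1:
        yield (n,)
        return
    for first in range(1, n - parts + 2):
        for rest in compositions(n - first, parts - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_checkable_statistic(self):
        """Three groups occupying rank blocks 1-3, 4-6, 7-9 give H = 7.2."""
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis_rank(values, labels)
        assert res.chi_square == pytest.approx(7.2, abs=1e-12)
        assert res.dof == 2

    def test_matches_oracle_on_all_small_partitions(self):
        """H agrees with the hand-rank oracle to 1e-12 on every group-size
        composition of N <= 9 into 2 or 3 groups, with and without ties."""
        rng = np.random.default_rng(42)
        for N in range(3, 10):
            for parts in (2, 3):
                if N < parts:
                    continue
                for sizes in compositions(N, parts):
                    for tied in (False, True):
                        if tied:
                            values = rng.integers(0, 4, N).astype(float)
                        else:
                            values = rng.permutation(N).astype(float)
                        if np.all(values == values[0]):
                            continue
                        labels = np.repeat(np.arange(parts), sizes)
                        groups = [values[labels == g] for g in range(parts)]
                        res = kruskal_wallis_rank(values, labels)
                        assert res.chi_square == pytest.approx(
                            kw_oracle(groups), abs=1e-12
                        )

    def test_all_tied_defined_as_null(self):
        res = kruskal_wallis_rank([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.chi_square == 0.0 and res.p_value == 1.0 and res.all_tied

    def test_two_group_H_equals_squared_standardized_rank_sum(self):
        """For two tie-free groups, H is the square of the standardized
        Wilcoxon rank-sum z (no continuity correction)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n2 = rng.integers(3, 15, 2)
            vals = rng.permutation(int(n1 + n2)).astype(float)
            a, b = vals[:n1], vals[n1:]
            ranks = midranks(vals)
            W = ranks[:n1].sum()
            N = n1 + n2
            z = (W - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12.0)
            res = kruskal_wallis_rank(vals, ["a"] * int(n1) + ["b"] * int(n2))
            assert res.chi_square == pytest.approx(z**2, abs=1e-9)

    def test_permutation_null_matches_chi_square_mean(self):
        """Mean of H over label permutations approximates the chi-square(2)
        mean (dof) within 5% at N = 60."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=60)
        labels = np.repeat([0, 1, 2], 20)
        hs = []
        for _ in range(2000):
            hs.append(kruskal_wallis_rank(values, rng.permutation(labels)).chi_square)
        assert np.mean(hs) == pytest.approx(2.0, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ChemometricsError):
            kruskal_wallis_rank([1, 2, 3], ["a", "a", "a"])


class TestWilcoxon:
    def test_exact_small_sample(self):
        """[1,2] vs [3,4]: most extreme of the C(4,2)=6 assignments -> 1/3."""
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_two_sided == pytest.approx(1 / 3, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == 1.0

    def test_matches_enumeration_oracle_on_small_partitions(self):
        rng = np.random.default_rng(3)
        for N in range(3, 10):
            for n1 in range(1, N):
                vals = rng.permutation(N * 10)[:N].astype(float)  # distinct
                a, b = vals[:n1], vals[n1:]
                res = wilcoxon_rank_sum(a, b)
                assert res.p_two_sided == pytest.approx(
                    wilcoxon_exact_oracle(a, b), abs=1e-12
                )
                assert res.statistic == pytest.approx(midranks(vals)[:n1].sum())

    def test_type_one_error_calibration(self):
        """Asymptotic branch rejects at ~alpha under the null (n=30 vs 30)."""
        rng = np.random.default_rng(4)
        n_rep, alpha = 1000, 0.05
        rejects = sum(
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30)).p_two_sided
            < alpha
            for _ in range(n_rep)
        )
        lo = sstats.binom.ppf(0.005, n_rep, alpha)
        hi = sstats.binom.ppf(0.995, n_rep, alpha)
        assert lo <= rejects <= hi

    def test_empty_input_errors(self):
        with pytest.raises(ChemometricsError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_identical_spectra_degenerate_variance(self, axis_small):
        X = np.tile(np.linspace(0, 1, axis_small.size), (3, 1))
        with pytest.raises(DegenerateVarianceError, match="degenerate"):
            fit_pca(X, k=1, axis=axis_small)

    def test_rank_two_mixture_concentrates_variance(self, axis_fp):
        rng = np.random.default_rng(5)
        b1 = gaussian(axis_fp, 800, 20) + gaussian(axis_fp, 1200, 15)
        b2 = gaussian(axis_fp, 1000, 25) + gaussian(axis_fp, 1600, 10)
        X = rng.uniform(0.5, 2.0, (40, 2)) @ np.vstack([b1, b2])
        model = fit_pca(X, k=5, axis=axis_fp)
        assert cumulative_evr(model, 2) >= 0.999
        assert cumulative_evr(model, 0) == 0.0

    def test_orthonormality_reconstruction_and_score_moments(self, axis_fp):
        rng = np.random.default_rng(6)
        n = 25
        X = rng.normal(size=(n, axis_fp.size))
        k = n - 1  # full rank (centered data)
        model = fit_pca(X, k=k, axis=axis_fp)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-10)
        scores = model.scores[model.pc_names()].to_numpy()
        recon = model.mean_spectrum + scores @ model.loadings
        assert np.max(np.abs(recon - X)) <= 1e-8 * np.max(np.abs(X))
        # per-component score moments: zero mean, sum of squares = evr * SS
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            (scores**2).sum(axis=0),
            model.evr * model.total_variance,
            rtol=1e-10,
        )
        assert cumulative_evr(model, k) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(model.evr) <= 1e-15)

    def test_k_exceeding_rank_errors(self, axis_small):
        X = np.random.default_rng(7).normal(size=(4, axis_small.size))
        with pytest.raises(ChemometricsError):
            fit_pca(X, k=4, axis=axis_small)

    def test_deterministic_sign_and_flip_covariance(self, axis_fp):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, axis_fp.size))
        model = fit_pca(X, k=3, axis=axis_fp)
        for i in range(3):
            j = np.argmax(np.abs(model.loadings[i]))
            assert model.loadings[i, j] > 0
        ref = -model.loadings[0]
        before = model.score_vector(1).copy()
        orient_to(model, ref, pc=1)
        np.testing.assert_allclose(model.score_vector(1), -before)
        assert model.orientation[0] in (-1.0, 1.0)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

class TestGroupStats:
    def test_prop_negative(self):
        (g,) = group_stats([-1.0, -2.0, 3.0, 4.0], ["x"] * 4)
        assert g.prop_negative == 0.5

    def test_notch_and_quartiles_match_hand_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        (g,) = group_stats(x, ["x"] * 100)
        q25, q75 = np.percentile(x, [25, 75])
        assert g.q25 == pytest.approx(q25) and g.q75 == pytest.approx(q75)
        assert g.notch_halfwidth == pytest.approx(1.57 * (q75 - q25) / 10.0)
        assert g.q25 <= g.median <= g.q75
        inside = x[(x >= q25 - 1.5 * (q75 - q25)) & (x <= q75 + 1.5 * (q75 - q25))]
        assert g.whisker_low == inside.min() and g.whisker_high == inside.max()

    def test_label_partition_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        labels1 = np.repeat(["a", "b", "c"], 10)
        labels2 = np.repeat(["g2", "g0", "g1"], 10)
        s1 = group_stats(x, labels1)
        s2 = group_stats(x, labels2)
        m1 = {tuple(np.flatnonzero(labels1 == g.label)): g.median for g in s1}
        m2 = {tuple(np.flatnonzero(labels2 == g.label)): g.median for g in s2}
        assert m1 == m2

    def test_empty_group_errors(self):
        with pytest.raises(ChemometricsError):
            group_stats([], [])

    def test_percentile_rule(self):
        assert percentile([1, 2, 3, 4, 5], 50) == 3
        assert percentile([0.0, 1.0], 25) == pytest.approx(0.25)
        assert percentile([7.0], 90) == 7.0

    def test_subject_segregation_classes(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 200)
        a2 = rng.normal(0.05, 1.0, 200)   # indistinguishable from a
        b = rng.normal(5.0, 1.0, 200)     # clearly separated
        values = np.concatenate([a, a2, b])
        subjects = np.repeat(["s1", "s2", "s3"], 200)
        classes = subject_segregation(values, subjects, alpha=0.05)
        assert classes == [["s1", "s2"], ["s3"]]


# ---------------------------------------------------------------------------
# component ranking
# ---------------------------------------------------------------------------

class TestRankComponents:
    def _model_with_dose_signal(self, seed=12, effect=2.0):
        rng = np.random.default_rng(seed)
        axis = np.arange(460.0, 1801.0)
        b1 = gaussian(axis, 900, 15)
        b2 = gaussian(axis, 1400, 15)
        doses = np.repeat([0.0, 5.0, 15.0], 40)
        w1 = rng.normal(5, 0.5, doses.size) + effect * (doses / 15.0)
        w2 = rng.normal(3, 0.5, doses.size)
        X = np.outer(w1, b1) + np.outer(w2, b2) + rng.normal(0, 0.01, (doses.size, axis.size))
        ids = [f"s{i:03d}" for i in range(doses.size)]
        md = make_metadata(ids, n_cols=12)
        md["dose_Gy"] = doses
        md["subject_id"] = [f"S{d:02.0f}" for d in doses]
        model = fit_pca(X, k=3, metadata=md, axis=axis, ids=ids)
        return model, doses

    def test_dose_bearing_component_ranks_first(self):
        model, doses = self._model_with_dose_signal()
        table = rank_components(model, doses)
        top = int(table["pc"].iloc[0])
        # the top-ranked component's scores must separate dose groups
        s = model.score_vector(top)
        assert kruskal_wallis_rank(s, doses).chi_square == table["chi_square"].iloc[0]
        assert table["chi_square"].iloc[0] > 5 * table["chi_square"].iloc[1]

    def test_shuffled_labels_consistent_with_null(self):
        """With labels shuffled, the max chi-square over 3 PCs stays below
        the chi-square(2) 99th percentile in most seeds."""
        model, doses = self._model_with_dose_signal()
        rng = np.random.default_rng(13)
        crit = sstats.chi2.ppf(0.99, 2)
        ok = 0
        n_seeds = 40
        for _ in range(n_seeds):
            table = rank_components(model, rng.permutation(doses))
            ok += table["chi_square"].iloc[0] <= crit
        assert ok / n_seeds >= 0.90

    def test_ratio_attribute(self):
        model, doses = self._model_with_dose_signal()
        table = rank_components(model, doses)
        expected = table["chi_square"].iloc[2] / table["chi_square"].iloc[1]
        assert table.attrs["ratio_3rd_to_2nd"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# loading annotation and correlation
# ---------------------------------------------------------------------------

class TestAnnotateLoading:
    def test_constructed_glycogen_vs_protein_loading(self, axis_fp):
        table = default_band_table()
        bases = make_basis_spectra(table.subset(["glycogen", "protein"]), axis_fp)
        loading = bases["protein"].to_numpy() - bases["glycogen"].to_numpy()
        ann = annotate_loading(loading, axis_fp, table)
        assert ann.side("glycogen") == "negative"
        assert ann.side("protein") == "positive"

    def test_single_band_is_not_assigned(self, axis_fp):
        table = default_band_table()
        loading = -gaussian(axis_fp, 1042.0, 4.0)  # lone glycogen trough
        ann = annotate_loading(loading, axis_fp, table)
        assert ann.side("glycogen") == "unassigned"

    def test_all_zero_loading_has_no_extrema(self, axis_fp):
        ann = annotate_loading(np.zeros(axis_fp.size), axis_fp, default_band_table())
        assert ann.extrema_positive == [] and ann.extrema_negative == []
        assert all(e.side == "unassigned" for e in ann.entries.values())

    def test_sign_flip_swaps_sides(self, axis_fp):
        table = default_band_table()
        bases = make_basis_spectra(table.subset(["glycogen", "protein"]), axis_fp)
        loading = bases["protein"].to_numpy() - bases["glycogen"].to_numpy()
        ann = annotate_loading(-loading, axis_fp, table)
        assert ann.side("glycogen") == "positive"
        assert ann.side("protein") == "negative"

    def test_both_sides_reported_mixed(self, axis_fp):
        table = default_band_table()
        loading = (
            gaussian(axis_fp, 482.0, 4.0) + gaussian(axis_fp, 850.0, 4.0)
            - gaussian(axis_fp, 1042.0, 4.0) - gaussian(axis_fp, 1129.0, 4.0)
        )
        ann = annotate_loading(loading, axis_fp, table)
        assert ann.side("glycogen") == "mixed"


class TestCorrelateLoadings:
    def test_identity_and_negation(self, axis_fp):
        v = gaussian(axis_fp, 1000, 30) - gaussian(axis_fp, 1400, 20)
        assert correlate_loadings(v, v).r == pytest.approx(1.0)
        assert correlate_loadings(v, -v).r == pytest.approx(-1.0)

    def test_overlap_resampling(self, axis_fp):
        axis_b = np.arange(600.0, 1700.0, 2.0)
        v = gaussian(axis_fp, 1000, 30)
        w = gaussian(axis_b, 1000, 30)
        res = correlate_loadings(v, w, axis_a=axis_fp, axis_b=axis_b)
        assert res.overlap == (600.0, 1698.0)
        assert res.r == pytest.approx(1.0, abs=1e-4)

    def test_disjoint_axes_error(self):
        with pytest.raises(ChemometricsError):
            correlate_loadings(
                np.ones(10), np.ones(10),
                axis_a=np.arange(500, 510), axis_b=np.arange(900, 910),
            )
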