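"""Median polish, association tests, BH, Fisher co-occurrence and PAGE."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pace.genetic_association import (
    assoc_test,
    association_scan,
    bh_adjust,
    fisher_cooccurrence,
    median_polish,
    page_enrichment,
    volcano_per_concentration,
)
from pace.screen_core import ViabilityTensor


class TestMedianPolish:
    def test_two_by_two_hand_decomposition(self):
        fit = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert fit.overall == pytest.approx(2.5)
        np.testing.assert_allclose(fit.row_effects, [-1.0, 1.0])
        np.testing.assert_allclose(fit.col_effects, [-0.5, 0.5])
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_constant_matrix(self):
        fit = median_polish(np.full((4, 5), 7.0))
        assert fit.overall == pytest.approx(7.0)
        np.testing.assert_allclose(fit.row_effects, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.col_effects, 0.0, atol=1e-12)

    def test_single_outlier_is_isolated_in_residuals(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(0, 5, 8)
        cols = rng.normal(0, 3, 5)
        m = 90.0 + rows[:, None] + cols[None, :]
        m[3, 2] += 40.0
        fit = median_polish(m)
        resid = np.abs(fit.residuals)
        outlier = resid[3, 2]
        resid[3, 2] = 0.0
        assert outlier > 10 * resid.max()

    @given(st.integers(min_value=0, max_value=10_000))
    def test_reconstruction_identity_and_scale_linearity(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(80, 20, (rng.integers(2, 7), rng.integers(2, 6)))
        fit = median_polish(m)
        recon = fit.overall + fit.row_effects[:, None] + fit.col_effects[None, :] + fit.residuals
        np.testing.assert_allclose(recon, m, atol=1e-9)
        fit2 = median_polish(2.0 * m)
        assert fit2.overall == pytest.approx(2.0 * fit.overall, abs=1e-9)
        np.testing.assert_allclose(fit2.row_effects, 2.0 * fit.row_effects, atol=1e-9)
        np.testing.assert_allclose(fit2.residuals, 2.0 * fit.residuals, atol=1e-9)

    def test_all_missing_row_dropped_with_warning(self):
        m = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="all-missing"):
            fit = median_polish(m)
        assert fit.row_kept.tolist() == [True, False, True]
        assert np.isnan(fit.row_effects_full[1])

    def test_degenerate_shape_raises(self):
        with pytest.raises(ValueError):
            median_polish(np.array([[1.0, 2.0]]))


class TestAssocTest:
    def test_exact_feature_effect(self):
        f = np.array([0.0] * 10 + [1.0] * 10)
        y = 90.0 + 10.0 * f
        effect, p = assoc_test(y, f)
        assert effect == pytest.approx(10.0)
        assert p < 1e-12

    def test_blocking_removes_confounded_effect(self):
        # feature effect entirely mediated by the block
        rng = np.random.default_rng(2)
        block = np.array([0.0] * 40 + [1.0] * 40)
        feature = block.copy()
        flip = rng.choice(80, 16, replace=False)  # partial overlap so both are estimable
        feature[flip] = 1.0 - feature[flip]
        y = 90.0 + 10.0 * block + rng.normal(0, 1, 80)
        eff_unblocked, _ = assoc_test(y, feature)
        eff_blocked, p_blocked = assoc_test(y, feature, block=block)
        assert abs(eff_unblocked) > 5.0
        assert abs(eff_blocked) < 1.0
        assert p_blocked > 0.01

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        f = np.array([0.0] * 20 + [1.0] * 20)
        pvals = []
        for _ in range(300):
            y = rng.normal(90, 8, 40)
            pvals.append(assoc_test(y, f)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_level_returns_nan_with_warning(self):
        y = np.arange(6, dtype=float)
        f = np.ones(6)
        with pytest.warns(UserWarning, match="<2 samples"):
            effect, p = assoc_test(y, f)
        assert np.isnan(effect) and np.isnan(p)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition: adj_(k) = min_{i >= k} min(1, p_(i) * m / i)."""
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adj, flags = bh_adjust([0.03], q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_tied_harmonic_example(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        adj, flags = bh_adjust([1.0, 1.0, 1.0])
        np.testing.assert_allclose(adj, 1.0)
        assert not flags.any()

    def test_nan_p_values_pass_through(self):
        adj, flags = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not flags[1]
        np.testing.assert_allclose(adj[[0, 2]], brute_force_bh(np.array([0.01, 0.5])))

    def test_matches_exhaustive_step_up_for_small_families(self):
        rng = np.random.default_rng(4)
        for m in range(1, 7):
            for _ in range(50):
                p = np.round(rng.random(m), 3)
                adj, flags = bh_adjust(p, q=0.1)
                expected = brute_force_bh(p)
                np.testing.assert_allclose(adj, expected, atol=1e-12)
                np.testing.assert_array_equal(flags, expected <= 0.1)
                assert np.all(adj >= p - 1e-15)  # adjusted never below raw


def fisher_enumeration_p(table: np.ndarray) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration (oracle)."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherCooccurrence:
    @staticmethod
    def _vectors(table):
        f1, f2 = [], []
        for (v1, v2), n in zip(((1, 1), (1, 0), (0, 1), (0, 0)), table.ravel()):
            f1 += [v1] * n
            f2 += [v2] * n
        return np.array(f1, float), np.array(f2, float)

    def test_independence_table(self):
        res = fisher_cooccurrence(*self._vectors(np.array([[5, 5], [5, 5]])))
        assert res.sample_odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_enriched_table_values(self):
        res = fisher_cooccurrence(*self._vectors(np.array([[8, 2], [2, 8]])))
        assert res.sample_odds_ratio == pytest.approx(16.0)
        assert res.p_value == pytest.approx(0.023, abs=5e-4)

    def test_perfect_cooccurrence_inf_sentinel(self):
        res = fisher_cooccurrence(*self._vectors(np.array([[10, 0], [0, 10]])))
        assert np.isinf(res.sample_odds_ratio)
        assert res.p_value == pytest.approx(1.08e-5, rel=5e-3)
        assert res.p_value == pytest.approx(fisher_enumeration_p(res.table), rel=1e-9)

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            table = rng.integers(0, 9, (2, 2))
            if table.sum() > 30 or table.sum(0).min() == 0 or table.sum(1).min() == 0:
                continue
            f1, f2 = self._vectors(table)
            if len(np.unique(f1)) < 2 or len(np.unique(f2)) < 2:
                continue
            res = fisher_cooccurrence(f1, f2)
            assert res.p_value == pytest.approx(fisher_enumeration_p(table), rel=1e-9)

    def test_constant_feature_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fisher_cooccurrence(np.ones(10), np.array([0, 1] * 5, float))

    def test_pairwise_complete_filtering(self):
        f1 = np.array([1, 1, 0, 0, np.nan, 1, 0, 1, 0, 0])
        f2 = np.array([1, 0, 0, 1, 1, np.nan, 0, 1, 1, 0])
        res = fisher_cooccurrence(f1, f2)
        assert res.table.sum() == 8


class TestPageEnrichment:
    def test_whole_universe_set_has_zero_z(self):
        stats_ = pd.Series(np.random.default_rng(6).normal(0, 1, 100),
                           index=[f"g{i}" for i in range(100)])
        res = page_enrichment(stats_, {"all": list(stats_.index)})
        assert res.z.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value.iloc[0] == pytest.approx(1.0)

    def test_single_gene_one_sd_above_mean_has_z_one(self):
        # universe (-1, 0, 1): mu = 0, sigma = 1, so gene 'c' sits at mu + sigma
        stats_ = pd.Series([-1.0, 0.0, 1.0], index=list("abc"))
        res = page_enrichment(stats_, {"solo": ["c"]})
        assert res.z.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        stats_ = pd.Series(rng.normal(2, 3, 200), index=[f"g{i}" for i in range(200)])
        sets = {"s1": [f"g{i}" for i in range(25)], "s2": [f"g{i}" for i in range(100, 140)]}
        base = page_enrichment(stats_, sets)
        mapped = page_enrichment(5.0 * stats_ + 11.0, sets)
        np.testing.assert_allclose(base.z.values, mapped.z.values, atol=1e-9)

    def test_planted_shift_matches_closed_form(self):
        # m = 25 genes shifted by 0.8 in a standard-normal universe: E[Z] ~ 0.8 * 5.
        # The universe must dwarf the planted set, else the shifted genes
        # contaminate mu and sigma and bias Z low.
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10_000)]
        zs = []
        for _ in range(1000):
            vals = rng.normal(0, 1, 10_000)
            vals[:25] += 0.8
            stats_ = pd.Series(vals, index=genes)
            zs.append(page_enrichment(stats_, {"s": genes[:25]}).z.iloc[0])
        assert np.mean(zs) == pytest.approx(4.0, abs=0.1)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            page_enrichment(pd.Series(dtype=float), {"s": ["g1"]})


def _planted_tensor(n=80, n_drugs=3, effect_concs=(0, 1), effect=-12.0, seed=0):
    """Tensor with an IGHV-like factor effect on drug 0 at selected concentrations."""
    rng = np.random.default_rng(seed)
    factor = pd.Series((rng.random(n) < 0.4).astype(float),
                       index=[f"S{i}" for i in range(n)])
    values = rng.normal(95, 3, (n, n_drugs, 5))
    for k in effect_concs:
        values[:, 0, k] += effect * factor.values
    tensor = ViabilityTensor(list(factor.index), [f"d{j}" for j in range(n_drugs)], values)
    return tensor, factor


class TestVolcano:
    def test_flags_confined_to_planted_concentrations(self):
        tensor, factor = _planted_tensor(effect_concs=(0, 1), seed=1)
        table = volcano_per_concentration(tensor, factor)
        sig = table[table.significant_at_q]
        assert set(zip(sig.drug_id, sig.concentration_index)) == {("d0", 1), ("d0", 2)}

    def test_sign_convention_sensitive_group_negative(self):
        tensor, factor = _planted_tensor(seed=2)
        table = volcano_per_concentration(tensor, factor)
        row = table[(table.drug_id == "d0") & (table.concentration_index == 1)].iloc[0]
        assert row.effect < 0  # factor-positive group more sensitive

    def test_null_flag_fraction_below_q(self):
        rng = np.random.default_rng(3)
        flagged = total = 0
        for s in range(40):
            tensor, factor = _planted_tensor(effect=0.0, seed=100 + s)
            table = volcano_per_concentration(tensor, factor)
            flagged += int(table.significant_at_q.sum())
            total += len(table)
        assert flagged / total <= 0.10


class TestAssociationScan:
    def test_zero_variance_drug_rows_missing(self):
        tensor, factor = _planted_tensor(seed=4)
        tensor.values[:, 1, :] = 88.0  # flat drug
        features = pd.DataFrame({"f": factor})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = association_scan(tensor, features)
        assert table[table.drug_id == "d1"]["p_value"].isna().all()

    def test_nonbinary_feature_skipped_with_warning(self):
        tensor, factor = _planted_tensor(seed=5)
        features = pd.DataFrame({"f": factor, "meth": factor * 0.5})
        with pytest.warns(UserWarning, match="meth"):
            table = association_scan(tensor, features)
        assert set(table.feature_id) == {"f"}

    def test_blocked_and_unblocked_concordant_without_confounding(self, cll_view):
        features = cll_view["features"].drop(columns=["methylation_cluster"])
        features = features[["trisomy12", "TP53", "del13q14", "del11q22.3"]]
        block = pd.Series(
            np.random.default_rng(6).integers(0, 2, len(features)).astype(float),
            index=features.index,
        )  # random block, unrelated to anything
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = association_scan(cll_view["tensor"], features)
            blocked = association_scan(cll_view["tensor"], features, block=block)
        logp = lambda t: -np.log10(t.set_index(["drug_id", "feature_id"]).p_value)
        a, b = logp(plain).align(logp(blocked), join="inner")
        ok = a.notna() & b.notna()
        rho = stats.spearmanr(a[ok], b[ok]).statistic
        assert rho > 0.95
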