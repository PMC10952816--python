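"""Covariate transforms: log10, z-scores, imputation, anchored PC1."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msam.exceptions import ValidationError
from msam.prep import (PrepConfig, impute_mean, log10_positive, pc1,
                       prepare_covariates, screen_correlations, zscore)
from msam.survey import SiteTable


class TestElementwise:
    def test_log10(self):
        assert np.allclose(log10_positive([1, 10, 100]), [0, 1, 2])
        assert log10_positive([284])[0] == pytest.approx(2.4533, abs=1e-4)
        with pytest.raises(ValidationError):
            log10_positive([1.0, 0.0])

    def test_zscore_hand_case(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])
        with pytest.raises(ValidationError):
            zscore([4, 4, 4])
        out = zscore([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and np.allclose(out[[0, 2]], [-0.7071, 0.7071], atol=1e-4)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40).filter(
        lambda v: np.std(v) > 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_zscore_standardises(self, values):
        z = zscore(values)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_impute_mean(self):
        assert np.allclose(impute_mean([1, np.nan, 3]), [1, 2, 3])
        x = np.array([1.0, 2.0])
        assert np.array_equal(impute_mean(x), x)
        with pytest.raises(ValidationError):
            impute_mean([np.nan, np.nan])

    def test_impute_then_zscore_idempotent(self):
        x = np.array([1.0, np.nan, 3.0, 6.0])
        once = zscore(impute_mean(x))
        assert np.allclose(zscore(impute_mean(once)), once)


class TestPc1:
    def block(self, rng, J=30, cols=("u", "v", "w")):
        X = rng.normal(size=(J, len(cols)))
        return pd.DataFrame(X, columns=list(cols))

    def test_duplicated_columns_explain_everything(self, rng):
        x = rng.normal(size=25)
        res = pc1(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.prop_variance == pytest.approx(1.0)

    def test_two_variable_proportion_from_correlation(self, rng):
        # correlation-matrix eigenvalues of a 2x2 block are 1 +/- r
        x = rng.normal(size=2000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=2000)
        res = pc1(pd.DataFrame({"a": x, "b": y}))
        r = np.corrcoef(x, y)[0, 1]
        assert res.prop_variance == pytest.approx((1 + abs(r)) / 2, abs=1e-9)

    def test_matches_svd_oracle(self, rng):
        block = self.block(rng)
        res = pc1(block)
        Z = (block - block.mean()) / block.std(ddof=1)
        _, _, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
        oracle = Z.to_numpy() @ Vt[0]
        sign = np.sign(oracle @ res.scores.to_numpy())
        assert np.allclose(res.scores.to_numpy(), sign * oracle, atol=1e-8)

    def test_anchor_orients_scores(self, rng):
        block = self.block(rng)
        res_neg = pc1(block, anchor=("u", -1))
        res_pos = pc1(block, anchor=("u", +1))
        assert res_neg.loadings["u"] <= 0 <= res_pos.loadings["u"]
        assert np.allclose(res_neg.scores, -res_pos.scores)

    def test_anchored_scores_invariant_to_column_negation(self, rng):
        block = self.block(rng)
        flipped = block.copy()
        flipped["v"] = -flipped["v"]
        a = pc1(block, anchor=("u", 1)).scores.to_numpy()
        b = pc1(flipped, anchor=("u", 1)).scores.to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_eigenvalue_proportions_sum_to_one(self, rng):
        res = pc1(self.block(rng, cols=list("abcde")))
        assert res.eigenvalues.sum() == pytest.approx(len("abcde"), abs=1e-9)

    def test_errors(self, rng):
        block = self.block(rng)
        block["u"] = 1.0
        with pytest.raises(ValidationError, match="zero-variance"):
            pc1(block)
        with pytest.raises(ValidationError, match="anchor"):
            pc1(self.block(rng), anchor=("missing", 1))


class TestScreening:
    def test_flags_fixture_pair(self, fixture_table):
        table, _ = fixture_table
        cols = {"pct_connected": table.data["pct_connected"].to_numpy(),
                "fish": table.data["large_fish_richness"].to_numpy()}
        hits = screen_correlations(cols, threshold=0.7)
        assert len(hits) == 1
        assert hits[0][2] == pytest.approx(0.703, abs=5e-4)

    def test_independent_columns_not_flagged(self, rng):
        cols = {f"c{i}": rng.normal(size=50) for i in range(4)}
        assert screen_correlations(cols, threshold=0.99) == []

    def test_sorted_by_magnitude_and_no_self_pairs(self, rng):
        x = rng.normal(size=100)
        cols = {"x": x, "y": 0.9 * x + 0.44 * rng.normal(size=100),
                "z": -0.99 * x + 0.14 * rng.normal(size=100)}
        hits = screen_correlations(cols, threshold=0.1)
        assert all(a != b for a, b, _ in hits)
        mags = [abs(r) for _, _, r in hits]
        assert mags == sorted(mags, reverse=True)


class TestPrepare:
    def make_sites(self, rng, J=20):
        data = pd.DataFrame({
            "sampled_area_m2": rng.uniform(300, 100_000, J),
            "nn_distance_m": rng.uniform(30, 6000, J),
            "large_fish_richness": rng.integers(0, 9, J),
            "pct_connected": rng.uniform(0, 100, J),
            "depth": rng.uniform(0.2, 4.0, J),
            "permanence": rng.integers(0, 2, J).astype(float),
            "forest": rng.uniform(0, 1, J),
            "agric": rng.uniform(0, 1, J),
            "pasture": rng.uniform(0, 1, J),
            "ph": rng.uniform(6, 9, J),
            "conductivity": rng.uniform(200, 900, J),
        }, index=[f"w{j}" for j in range(J)])
        data.loc["w3", "ph"] = np.nan  # chemistry gaps are allowed
        blocks = {"hydrology": ["pct_connected", "depth", "permanence"],
                  "landscape": ["forest", "agric", "pasture"],
                  "chemistry": ["ph", "conductivity"]}
        return SiteTable(data, blocks)

    def test_full_preparation(self, rng):
        sites = self.make_sites(rng)
        prep = prepare_covariates(sites, config=PrepConfig())
        for name in ("area", "distance", "fish", "hydrology", "landscape", "water"):
            col = prep.site[name]
            assert abs(col.mean()) < 1e-9 and abs(col.std(ddof=1) - 1) < 1e-9
        # hydrology anchored so connectivity loads negative
        assert prep.pca["hydrology"].loadings["pct_connected"] < 0
        assert prep.pca["landscape"].loadings["forest"] < 0

    def test_design_matrix_has_intercept(self, rng):
        prep = prepare_covariates(self.make_sites(rng), config=PrepConfig())
        X = prep.design_matrix(["area", "hydrology"])
        assert X.shape == (20, 3)
        assert np.all(X[:, 0] == 1.0)
        with pytest.raises(KeyError):
            prep.design_matrix(["nonexistent"])
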