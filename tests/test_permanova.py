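import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from nichepart.permanova import bray_curtis, permanova
from nichepart.core.types import ValidationError


def euclid(y):
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    return squareform(pdist(y))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[1.0, 2, 3], [1, 2, 3]]))
        assert d.d[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[5.0, 0, 0], [0, 3, 2.0]]))
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        d = bray_curtis(np.array([[80.0, 20, 0], [40, 40, 20]]))
        assert d.d[0, 1] == pytest.approx(0.4)

    def test_matches_scipy(self, rng):
        X = rng.uniform(0, 100, size=(8, 6))
        ours = bray_curtis(X).d
        theirs = squareform(pdist(X, metric="braycurtis"))
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            bray_curtis(np.array([[1.0, 2, 3], [0, 0, 0.0]]))

    def test_similarity_percent(self):
        d = bray_curtis(np.array([[80.0, 20, 0], [40, 40, 20]]))
        assert d.similarity_percent()[0, 1] == pytest.approx(60.0)


class TestPermanovaOracles:
    def test_one_way_euclidean_equals_classical_F(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        table = permanova(euclid(y), pd.DataFrame({"g": g}), ["g"], n_perm=49, seed=0)
        f_classic = f_oneway(y[:10], y[10:20], y[20:]).statistic
        assert table["g"]["pseudo_F"] == pytest.approx(f_classic, abs=1e-8)

    def test_multivariate_euclidean_equals_manova_trace_F(self, rng):
        # classical F computed from raw sums of squares, independent path
        Y = rng.normal(size=(15, 4))
        g = np.repeat(["a", "b", "c"], 5)
        table = permanova(euclid(Y), pd.DataFrame({"g": g}), ["g"], n_perm=49, seed=0)
        grand = Y.mean(axis=0)
        ss_total = ((Y - grand) ** 2).sum()
        ss_within = sum(((Y[g == lv] - Y[g == lv].mean(axis=0)) ** 2).sum() for lv in "abc")
        ss_between = ss_total - ss_within
        f_expected = (ss_between / 2) / (ss_within / 12)
        assert table["g"]["pseudo_F"] == pytest.approx(f_expected, abs=1e-8)

    def test_exhaustive_enumeration_exact_p(self, rng):
        y = rng.normal(size=6)
        g = np.array(["a"] * 3 + ["b"] * 3)
        table = permanova(euclid(y), pd.DataFrame({"g": g}), ["g"], n_perm=999, seed=0)
        assert table["g"]["exhaustive"]
        f_obs = f_oneway(y[g == "a"], y[g == "b"]).statistic
        count = 0
        for idx in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            if f_oneway(y[mask], y[~mask]).statistic >= f_obs - 1e-12:
                count += 1
        assert table["g"]["p_perm"] == pytest.approx(count / 20, abs=1e-15)


class TestPermanovaStructure:
    def three_factor_design(self, rng):
        levels = [(s, h, m) for s in "ABC" for h in "XYZ" for m in "PQR"]
        factors = pd.DataFrame(levels, columns=["species", "habitat", "season"])
        X = rng.uniform(1, 100, size=(27, 6))
        return bray_curtis(X), factors

    def test_ss_decomposition_balanced(self, rng):
        dmat, factors = self.three_factor_design(rng)
        terms = ["species", "habitat", "season", "species:habitat", "species:season", "habitat:season"]
        table = permanova(dmat, factors, terms, n_perm=19, seed=0)
        df = table.to_dataframe().set_index("term")
        ss_sum = df.loc[terms, "SS"].sum() + df.loc["Residual", "SS"]
        assert ss_sum == pytest.approx(df.loc["Total", "SS"], abs=1e-8)
        assert df.loc[terms, "df"].sum() + df.loc["Residual", "df"] == 26
        assert df.loc["Residual", "df"] == 8  # 2*2*2 with cell means

    def test_three_way_interaction_refused(self, rng):
        dmat, factors = self.three_factor_design(rng)
        terms = ["species", "habitat", "season", "species:habitat", "species:season",
                 "habitat:season", "species:habitat:season"]
        with pytest.raises(ValidationError, match="residual degrees of freedom"):
            permanova(dmat, factors, terms, n_perm=19, seed=0)

    def test_zero_df_term_rejected(self, rng):
        y = rng.normal(size=6)
        factors = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "g2": ["a"] * 3 + ["b"] * 3})
        with pytest.raises(ValidationError, match="zero degrees of freedom"):
            permanova(euclid(y), factors, ["g", "g2"], n_perm=9, seed=0)

    def test_identical_rows_undefined_not_zero(self):
        X = np.tile([10.0, 20, 30, 0, 0, 40], (6, 1))
        dmat = bray_curtis(X)
        factors = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3})
        table = permanova(dmat, factors, ["g"], n_perm=99, seed=0)
        assert table.degenerate
        assert np.isnan(table["g"]["pseudo_F"])
        assert np.isnan(table["g"]["p_perm"])

    def test_missing_factor_level_rejected(self, rng):
        y = rng.normal(size=4)
        factors = pd.DataFrame({"g": ["a", "b", None, "b"]})
        with pytest.raises(ValidationError, match="fully specified"):
            permanova(euclid(y), factors, ["g"], n_perm=9, seed=0)

    def test_seeded_reproducibility(self, rng):
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        t1 = permanova(euclid(y), pd.DataFrame({"g": g}), ["g"], n_perm=199, seed=7)
        t2 = permanova(euclid(y), pd.DataFrame({"g": g}), ["g"], n_perm=199, seed=7)
        assert t1["g"]["p_perm"] == t2["g"]["p_perm"]

    def test_unbalanced_design_runs(self, rng):
        X = rng.uniform(1, 100, size=(10, 6))
        factors = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3 + ["c"] * 4,
                                "h": (["u", "v"] * 5)})
        table = permanova(bray_curtis(X), factors, ["g", "h"], n_perm=99, seed=0)
        df = table.to_dataframe().set_index("term")
        assert df.loc["g", "df"] == 2 and df.loc["h", "df"] == 1
        assert 0 < df.loc["g", "p_perm"] <= 1


class TestNullCalibration:
    def test_super_uniformity_small(self):
        # quick version of the acceptance check: 60 null datasets
        hits = 0
        for rep in range(60):
            r = np.random.default_rng(5000 + rep)
            y = r.normal(size=18)
            g = np.repeat(["a", "b", "c"], 6)
            t = permanova(euclid(y), pd.DataFrame({"g": g}), ["g"], n_perm=199, seed=rep)
            hits += t["g"]["p_perm"] <= 0.05
        assert hits / 60 <= 0.15
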