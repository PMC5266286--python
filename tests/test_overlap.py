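import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nichepart.overlap import (
    habitat_overlap_matrix,
    overlap_matrix,
    pairwise_table,
    schoener_alpha,
    year_merge_check,
)
from nichepart.core.types import ValidationError


def brute_force_alpha(x, y):
    """Independent oracle: explicit loop over 1 - 0.5 * L1."""
    total = 0.0
    for a, b in zip(x, y):
        total += abs(a - b)
    return 1.0 - 0.5 * total


simplex6 = arrays(np.float64, 6, elements=st.floats(0.001, 1.0)).map(
    lambda v: v / v.sum()
)


class TestSchoenerAlpha:
    def test_identical_profiles_complete_overlap(self):
        p = np.array([0.2, 0.3, 0.1, 0.15, 0.15, 0.1])
        assert schoener_alpha(p, p) == 1.0

    def test_disjoint_support_no_overlap(self):
        assert schoener_alpha([1, 0, 0], [0, 1, 0]) == 0.0

    def test_hand_example(self):
        # 1 - 0.5*(0.4 + 0.1 + 0.5) = 0.5
        assert schoener_alpha([0.6, 0.4, 0.0], [0.2, 0.3, 0.5]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            schoener_alpha([1.0], [0.5, 0.5])

    def test_non_normalized_rejected(self):
        with pytest.raises(ValidationError, match="sums to"):
            schoener_alpha([0.5, 0.6], [0.5, 0.5])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            schoener_alpha([-0.1, 1.1], [0.5, 0.5])

    @given(x=simplex6, y=simplex6)
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_symmetric(self, x, y):
        a = schoener_alpha(x, y)
        assert a == pytest.approx(brute_force_alpha(x, y), abs=1e-12)
        assert a == pytest.approx(schoener_alpha(y, x), abs=1e-15)
        assert 0.0 <= a <= 1.0

    @given(x=simplex6, eps=st.floats(0.0, 0.05))
    @settings(max_examples=50, deadline=None)
    def test_moving_mass_changes_alpha_by_at_most_eps(self, x, eps):
        i, j = int(np.argmax(x)), int(np.argmin(x))
        if i == j:
            return
        eps = min(eps, x[i])
        y = x.copy()
        y[i] -= eps
        y[j] += eps
        assert abs(schoener_alpha(x, x) - schoener_alpha(x, y)) <= eps + 1e-12


class TestOverlapMatrix:
    def profiles(self):
        zoo = np.array([0.1, 0.62, 0.08, 0.1, 0.1, 0.0])
        benthic = np.array([0.0, 0.05, 0.05, 0.5, 0.3, 0.1])
        return {
            ("charr", "littoral", "June"): zoo,
            ("whitefish", "littoral", "June"): zoo.copy(),
            ("trout", "littoral", "June"): benthic,
        }

    def test_threshold_boundary(self):
        p = {("charr", "littoral", "June"): np.array([0.72, 0.28, 0, 0, 0, 0.0]),
             ("whitefish", "littoral", "June"): np.array([1.0, 0, 0, 0, 0, 0.0])}
        (res,) = overlap_matrix(p, threshold=0.60)
        assert res.alpha == pytest.approx(0.72)
        assert res.significant  # 0.72 >= 0.60

        p[("charr", "littoral", "June")] = np.array([0.59, 0.41, 0, 0, 0, 0.0])
        (res,) = overlap_matrix(p, threshold=0.60)
        assert res.alpha == pytest.approx(0.59)
        assert not res.significant

    def test_exact_threshold_is_significant(self):
        p = {("charr", "littoral", "June"): np.array([0.6, 0.4, 0, 0, 0, 0.0]),
             ("whitefish", "littoral", "June"): np.array([1.0, 0, 0, 0, 0, 0.0])}
        (res,) = overlap_matrix(p, threshold=0.60)
        assert res.alpha == pytest.approx(0.60)
        assert res.significant

    def test_absent_species_gives_no_row_and_dash(self):
        p = self.profiles()
        del p[("trout", "littoral", "June")]
        results = overlap_matrix(p)
        pairs = {r.pair for r in results}
        assert ("charr", "whitefish") in pairs
        assert ("charr", "trout") not in pairs
        table = pairwise_table(results)
        row = table[table.pair == "charr vs whitefish"].iloc[0]
        assert row["June"] == "100"
        assert row["August"] == "-"

    def test_identical_species_profiles_give_alpha_one(self):
        results = overlap_matrix(self.profiles())
        by_pair = {r.pair: r for r in results}
        assert by_pair[("charr", "whitefish")].alpha == 1.0


class TestHabitatOverlap:
    def cells(self, counts):
        """counts: {(species, habitat): n fish in June}."""
        from nichepart.catch import compute_cpue
        from nichepart.core.types import EffortRecord
        from conftest import make_fish

        eff = [EffortRecord(habitat=h, month="June", year=2005, net_area=100.0, nights=1)
               for h in ("littoral", "profundal", "pelagic")]
        fish = [make_fish(fish_id=f"{sp}{hab}{i}", species=sp, habitat=hab)
                for (sp, hab), n in counts.items() for i in range(n)]
        return compute_cpue(fish, eff)

    def test_cpue_share_profiles_feed_alpha(self):
        # charr 75/25/0 vs whitefish 25/75/0: alpha = 1 - 0.5*(0.5+0.5) = 0.5
        cells = self.cells({("charr", "littoral"): 3, ("charr", "profundal"): 1,
                            ("whitefish", "littoral"): 1, ("whitefish", "profundal"): 3})
        results = habitat_overlap_matrix(cells)
        (res,) = [r for r in results if r.pair == ("charr", "whitefish")]
        assert res.alpha == pytest.approx(0.5)
        assert not res.significant

    def test_species_with_no_catch_absent(self):
        cells = self.cells({("charr", "littoral"): 2, ("whitefish", "littoral"): 2})
        pairs = {r.pair for r in habitat_overlap_matrix(cells)}
        assert pairs == {("charr", "whitefish")}  # trout uncaught, no profile

    def test_identical_habitat_use_full_overlap(self):
        cells = self.cells({("charr", "pelagic"): 4, ("whitefish", "pelagic"): 2})
        (res,) = [r for r in habitat_overlap_matrix(cells) if r.pair == ("charr", "whitefish")]
        assert res.alpha == 1.0
        assert res.significant


class TestYearMergeCheck:
    def test_identical_years_merge(self):
        p = {"charr": np.array([0.5, 0.5, 0, 0, 0, 0.0])}
        decision = year_merge_check({2005: p, 2006: {k: v.copy() for k, v in p.items()}})
        assert decision.merge
        assert decision.alphas["charr"] == 1.0

    def test_discordant_group_blocks_merge(self):
        y1 = {"charr": np.array([1.0, 0, 0, 0, 0, 0.0]),
              "trout": np.array([0.5, 0.5, 0, 0, 0, 0.0])}
        y2 = {"charr": np.array([0.3, 0.7, 0, 0, 0, 0.0]),
              "trout": np.array([0.5, 0.5, 0, 0, 0, 0.0])}
        decision = year_merge_check({2005: y1, 2006: y2})
        assert not decision.merge
        assert decision.failures == ["charr"]
        assert decision.alphas["charr"] == pytest.approx(0.3)

    def test_group_missing_in_one_year_skipped(self):
        y1 = {"charr": np.array([1.0, 0, 0, 0, 0, 0.0]), "trout": np.array([1.0, 0, 0, 0, 0, 0.0])}
        y2 = {"charr": np.array([1.0, 0, 0, 0, 0, 0.0])}
        decision = year_merge_check({2005: y1, 2006: y2})
        assert decision.merge
        assert decision.skipped == ["trout"]

    def test_needs_exactly_two_years(self):
        with pytest.raises(ValidationError, match="two years"):
            year_merge_check({2005: {}})
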