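"""CWM and Rao quadratic entropy on Gower distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frost.community import (CommunityMatrix, TraitVector,
                             community_weighted_mean, exclude_engineer,
                             functional_components_table, gower_distance,
                             rao_fd)
from frost.errors import InputError


def brute_force_rao(cover: dict, values: dict, trait_range: float) -> float:
    """Independent oracle: explicit double sum over ordered species pairs."""
    keep = [s for s in cover if cover[s] > 0 and s in values]
    total = sum(cover[s] for s in keep)
    p = {s: cover[s] / total for s in keep}
    return sum(p[i] * p[j] * min(1.0, abs(values[i] - values[j]) / trait_range)
               for i, j in itertools.product(keep, keep))


def _trait(values: dict, trait_id="LT50") -> TraitVector:
    return TraitVector(trait_id, pd.Series(values, dtype=float))


class TestGower:
    def test_identity_and_extremes(self):
        assert gower_distance(-7.0, -7.0, 10.0) == 0.0
        assert gower_distance(-19.0, -9.0, 10.0) == 1.0
        assert gower_distance(-4.0, -9.0, 10.0) == 0.5

    def test_nonpositive_range_rejected(self):
        with pytest.raises(InputError):
            gower_distance(1.0, 2.0, 0.0)

    @given(st.floats(-20, 0), st.floats(-20, 0))
    def test_bounded_and_symmetric(self, a, b):
        d = gower_distance(a, b, 10.0)
        assert 0.0 <= d <= 1.0
        assert d == gower_distance(b, a, 10.0)


class TestCWM:
    def test_monoculture_identity(self):
        assert community_weighted_mean({"A": 30.0}, _trait({"A": -7.2})) == -7.2

    def test_equal_weights(self):
        cwm = community_weighted_mean({"A": 20.0, "B": 20.0},
                                      _trait({"A": 2.0, "B": 4.0}))
        assert cwm == pytest.approx(3.0, abs=1e-12)

    def test_three_species_hand_value(self):
        cwm = community_weighted_mean({"A": 50.0, "B": 30.0, "C": 20.0},
                                      _trait({"A": 0.0, "B": 5.0, "C": 10.0}))
        assert cwm == pytest.approx(3.5, abs=1e-12)

    def test_bounded_by_present_extremes_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            species = [f"s{i}" for i in range(rng.integers(2, 7))]
            cover = {s: float(rng.uniform(0.1, 10)) for s in species}
            values = {s: float(rng.uniform(-19, -5)) for s in species}
            trait = _trait(values)
            cwm = community_weighted_mean(cover, trait)
            assert min(values.values()) - 1e-12 <= cwm <= max(values.values()) + 1e-12
            doubled = community_weighted_mean(
                {s: 2 * c for s, c in cover.items()}, trait)
            assert cwm == pytest.approx(doubled, abs=1e-12)

    def test_missing_trait_species_dropped_before_normalization(self):
        cwm = community_weighted_mean({"A": 50.0, "B": 50.0},
                                      _trait({"A": -8.0, "B": np.nan}))
        assert cwm == -8.0


class TestRao:
    def test_monoculture_is_zero(self):
        assert rao_fd({"A": 10.0}, _trait({"A": -7.0, "B": -17.0})) == 0.0

    def test_two_species_maximal_distance(self):
        fd = rao_fd({"A": 10.0, "B": 10.0}, _trait({"A": 0.0, "B": 10.0}))
        assert fd == pytest.approx(0.5, abs=1e-12)

    def test_three_species_hand_value(self):
        fd = rao_fd({"A": 50.0, "B": 30.0, "C": 20.0},
                    _trait({"A": 0.0, "B": 5.0, "C": 10.0}))
        assert fd == pytest.approx(0.41, abs=1e-12)

    def test_agrees_with_brute_force_on_random_communities(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(1, 7))
            species = [f"s{i}" for i in range(n)]
            cover = {s: float(rng.uniform(0.1, 20)) for s in species}
            values = {s: float(rng.uniform(-19, -5)) for s in species}
            trait = _trait(values)
            if trait.range <= 0:
                continue
            assert rao_fd(cover, trait) == pytest.approx(
                brute_force_rao(cover, values, trait.range), abs=1e-12)

    def test_two_species_maximized_at_even_abundance(self):
        trait = _trait({"A": -5.0, "B": -15.0})
        scan = {p: rao_fd({"A": p, "B": 1.0 - p}, trait)
                for p in np.linspace(0.05, 0.95, 19)}
        assert max(scan, key=scan.get) == pytest.approx(0.5)
        p = 0.3
        assert scan[p] == pytest.approx(2 * p * (1 - p) * 1.0, abs=1e-12)

    @settings(deadline=None)
    @given(st.integers(0, 1000))
    def test_bounded_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        species = [f"s{i}" for i in range(4)]
        cover = {s: float(rng.uniform(0.1, 10)) for s in species}
        trait = _trait({s: float(rng.uniform(-19, -5)) for s in species})
        fd = rao_fd(cover, trait)
        assert 0.0 <= fd <= 1.0
        assert fd == pytest.approx(
            rao_fd({s: 3 * c for s, c in cover.items()}, trait), abs=1e-12)


def _matrix():
    cover = pd.DataFrame(
        [[60.0, 20.0, 20.0, 0.0], [50.0, 0.0, 25.0, 25.0]],
        index=pd.Index(["p1", "p2"], name="plot_id"),
        columns=["Eng", "A", "B", "C"])
    alt = pd.Series([2000.0, 2200.0], index=cover.index, name="altitude_m")
    return CommunityMatrix(cover, alt)


class TestEngineerExclusion:
    def test_engineer_removed_everywhere(self):
        out = exclude_engineer(_matrix(), "Eng")
        assert "Eng" not in out.cover.columns

    def test_absent_engineer_warns_and_is_noop(self):
        cm = _matrix()
        with pytest.warns(UserWarning, match="not present"):
            out = exclude_engineer(cm, "Nope")
        assert out.cover.equals(cm.cover)

    def test_emptied_plot_flagged_downstream(self):
        cover = pd.DataFrame([[100.0, 0.0]],
                             index=pd.Index(["p1"], name="plot_id"),
                             columns=["Eng", "A"])
        cm = CommunityMatrix(cover, pd.Series([2000.0], index=cover.index))
        out = exclude_engineer(cm, "Eng")
        table = functional_components_table(out, [_trait({"A": -8.0, "B": -9.0})])
        assert np.isnan(table["cwm"]).all()


class TestComponentsTable:
    def test_matches_hand_computation_per_plot(self):
        trait = _trait({"A": -5.0, "B": -10.0, "C": -15.0})
        table = functional_components_table(_matrix(), [trait], exclude="Eng")
        t = table.set_index("plot_id")
        assert t.loc["p1", "cwm"] == pytest.approx(-7.5, abs=1e-12)
        assert t.loc["p1", "fd_rao"] == pytest.approx(
            brute_force_rao({"A": 20, "B": 20}, {"A": -5.0, "B": -10.0}, 10.0),
            abs=1e-12)
        assert t.loc["p2", "cwm"] == pytest.approx(-12.5, abs=1e-12)

    def test_shared_trait_value_collapses_diversity(self):
        trait = _trait({"A": -8.0, "B": -8.0, "C": -8.0})
        table = functional_components_table(_matrix(), [trait], exclude="Eng")
        assert np.allclose(table["fd_rao"], 0.0)
        assert np.allclose(table["cwm"], -8.0)

    def test_cover_rescaling_leaves_outputs_unchanged(self):
        cm = _matrix()
        doubled = CommunityMatrix(cm.cover * 2.0, cm.altitude_m)
        trait = _trait({"A": -5.0, "B": -10.0, "C": -15.0})
        a = functional_components_table(cm, [trait], exclude="Eng")
        b = functional_components_table(doubled, [trait], exclude="Eng")
        assert np.allclose(a["cwm"], b["cwm"])
        assert np.allclose(a["fd_rao"], b["fd_rao"])

    def test_no_species_overlap_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            functional_components_table(_matrix(), [_trait({"X": -8.0,
                                                            "Y": -9.0})])
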