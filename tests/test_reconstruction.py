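import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srpkit import reconstruction as rc

from conftest import tau_oracle


def profile_frame(mles):
    return pd.DataFrame(
        {
            "species_id": [f"s{i}" for i in range(len(mles))],
            "n_localities": 1,
            "mle_km": mles,
        }
    )


class TestKendallTauB:
    def test_identity_and_reversal(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert rc.kendall_tau_b(x, x) == pytest.approx(1.0)
        assert rc.kendall_tau_b(x, x[::-1]) == pytest.approx(-1.0)

    def test_all_tied_is_flagged_not_zero(self):
        assert math.isnan(rc.kendall_tau_b([1, 1, 1, 1], [1, 2, 3, 4]))
        assert math.isnan(rc.kendall_tau_b([1, 2, 3, 4], [2, 2, 2, 2]))

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            rc.kendall_tau_b([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            rc.kendall_tau_b([1, 2], [1, 2])

    def test_exhaustive_small_vectors_match_pair_oracle(self):
        # every (x, y) pair over a 3-value alphabet at n = 3, 4
        for n in (3, 4):
            for x in itertools.product((1, 2, 3), repeat=n):
                for y in itertools.product((1, 2, 3), repeat=n):
                    got = rc.kendall_tau_b(x, y)
                    want = tau_oracle(x, y)
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_ties_match_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 4, n)
            got = rc.kendall_tau_b(x, y)
            want = stats.kendalltau(x, y).statistic
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestAdditionOrder:
    def test_distinct_mles_sort_deterministically(self):
        prof = profile_frame([5.0, 1.0, 3.0, 2.0, 4.0])
        rng = np.random.default_rng(0)
        asc = rc.addition_order(prof, "ascending", rng)
        assert list(asc) == ["s1", "s3", "s2", "s4", "s0"]
        desc = rc.addition_order(prof, "descending", np.random.default_rng(1))
        assert list(desc) == ["s0", "s4", "s2", "s3", "s1"]

    def test_all_tied_is_a_uniform_permutation(self):
        prof = profile_frame([0.0, 0.0, 0.0])
        counts = {}
        rng = np.random.default_rng(2)
        for _ in range(1200):
            key = tuple(rc.addition_order(prof, "ascending", rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        # chi-square against uniform over the 3! orderings, coarse bound
        chi2 = sum((c - 200) ** 2 / 200 for c in counts.values())
        assert chi2 < 20.1  # chi2(0.999, df=5)

    def test_single_site_only_tie_policy(self):
        prof = profile_frame([0.0, 0.0, 7.0, 7.0])
        rng = np.random.default_rng(3)
        orders = {tuple(rc.addition_order(prof, "ascending", rng, "single_site_only")) for _ in range(50)}
        # the 7-km tie block is never reshuffled, the 0-km block is
        assert all(o[2:] == ("s2", "s3") for o in orders)
        assert len({o[:2] for o in orders}) == 2

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            rc.addition_order(profile_frame([1, 2]), "sideways", np.random.default_rng(0))


def toy_system():
    """4 species over 5 cells with hand-checkable occupancies."""
    species_cells = {
        "s0": np.array([0]),
        "s1": np.array([0, 1]),
        "s2": np.array([0, 1, 2]),
        "s3": np.array([0, 1, 2, 3, 4]),
    }
    overall = np.array([4.0, 3.0, 2.0, 1.0, 1.0])
    return species_cells, overall


class TestStepwiseCurve:
    def test_full_subset_reaches_tau_one(self):
        species_cells, overall = toy_system()
        taus = rc.stepwise_curve(["s0", "s1", "s2", "s3"], species_cells, overall)
        assert taus[-1] == pytest.approx(1.0)

    def test_single_species_on_richest_cells_is_positive(self):
        species_cells, overall = toy_system()
        taus = rc.stepwise_curve(["s2", "s3", "s1", "s0"], species_cells, overall)
        assert taus[0] > 0

    def test_incremental_matches_recompute_from_scratch(self, make_assemblage, recon_inputs):
        recs = make_assemblage(n_species=30, seed=5)
        prof, species_cells, overall, _ = recon_inputs(recs)
        rng = np.random.default_rng(0)
        order = rc.addition_order(prof, "descending", rng)
        taus = rc.stepwise_curve(order, species_cells, overall)
        for k in (1, len(order) // 2, len(order)):
            sub = np.zeros_like(overall)
            for sp in order[:k]:
                sub[species_cells[sp]] += 1
            want = rc.kendall_tau_b(sub, overall)
            if math.isnan(want):
                assert math.isnan(taus[k - 1])
            else:
                assert taus[k - 1] == pytest.approx(want, abs=1e-12)

    def test_subset_cell_policy(self):
        species_cells, overall = toy_system()
        taus = rc.stepwise_curve(["s3", "s2", "s1", "s0"], species_cells, overall, cells="subset")
        # first step: subset occupies all 5 cells with richness 1 -> all tied
        assert math.isnan(taus[0])


class TestMedianCurveAndNull:
    def test_no_ties_median_equals_single_curve(self):
        species_cells, overall = toy_system()
        prof = profile_frame([1.0, 2.0, 3.0, 4.0])
        curves = [
            rc.median_curve(prof, species_cells, overall, "ascending", R, np.random.default_rng(R))
            for R in (1, 7)
        ]
        assert np.allclose(curves[0].tau_b, curves[1].tau_b, equal_nan=True)
        order = rc.addition_order(prof, "ascending", np.random.default_rng(0))
        raw = rc.stepwise_curve(order, species_cells, overall)
        assert np.allclose(curves[0].tau_b, raw, equal_nan=True)

    def test_median_converges_across_replicate_counts(self, make_assemblage, recon_inputs):
        recs = make_assemblage(n_species=40, seed=7)
        prof, species_cells, overall, _ = recon_inputs(recs)
        m1 = rc.median_curve(prof, species_cells, overall, "ascending", 200, np.random.default_rng(1))
        m2 = rc.median_curve(prof, species_cells, overall, "ascending", 400, np.random.default_rng(2))
        diffs = np.abs(m1.tau_b - m2.tau_b)
        assert np.nanmax(diffs) < 0.12  # Monte-Carlo agreement

    def test_final_step_null_envelope_is_degenerate(self):
        species_cells, overall = toy_system()
        prof = profile_frame([1.0, 2.0, 3.0, 4.0])
        null = rc.null_model(prof, species_cells, overall, 50, np.random.default_rng(3))
        assert np.allclose(null.taus[:, -1], 1.0)
        assert null.hi95[-1] - null.lo95[-1] == pytest.approx(0.0)

    def test_null_median_stable_across_seeds(self, make_assemblage, recon_inputs):
        recs = make_assemblage(n_species=40, seed=7)
        prof, species_cells, overall, _ = recon_inputs(recs)
        n1 = rc.null_model(prof, species_cells, overall, 300, np.random.default_rng(10))
        n2 = rc.null_model(prof, species_cells, overall, 300, np.random.default_rng(20))
        assert np.nanmax(np.abs(n1.median - n2.median)) < 0.12

    def test_pct_axes_are_nondecreasing_and_end_at_100(self, make_assemblage, recon_inputs):
        recs = make_assemblage(n_species=30, seed=5)
        prof, species_cells, overall, _ = recon_inputs(recs)
        curve = rc.median_curve(prof, species_cells, overall, "descending", 20, np.random.default_rng(4))
        assert np.all(np.diff(curve.pct_species) > 0)
        assert np.all(np.diff(curve.pct_ci) >= -1e-12)
        assert curve.pct_species[-1] == pytest.approx(100.0)
        assert curve.pct_ci[-1] == pytest.approx(100.0)
        assert curve.tau_b[-1] == pytest.approx(1.0)


class TestEmpiricalP:
    def test_at_null_median_p_is_one(self):
        null = np.linspace(-0.5, 0.5, 99)
        assert rc.empirical_p(0.0, null) == pytest.approx(1.0)

    def test_more_extreme_than_all_replicates(self):
        null = np.zeros(199) + np.linspace(-0.1, 0.1, 199)
        assert rc.empirical_p(0.9, null) == pytest.approx(1 / 200)

    def test_matches_hand_enumeration(self):
        null = np.array([0.0, 0.1, 0.2, 0.3, 0.4])  # median 0.2
        # |obs-0.2| = 0.15; replicates at distance >= 0.15: 0.0 (0.2) and 0.4? (0.2)
        # distances: .2,.1,0,.1,.2 -> two >= .15 -> p = (1+2)/6
        assert rc.empirical_p(0.35, null) == pytest.approx(3 / 6)

    def test_undefined_tau_gives_nan(self):
        assert math.isnan(rc.empirical_p(float("nan"), np.array([0.1, 0.2, 0.3])))


class TestCumulativeInformation:
    def test_trivial_contributions(self):
        # species occupying all cells adds 0; a half-prevalent species 0.25
        species_cells = {"full": np.arange(10), "half": np.arange(5)}
        ci, _ = rc.cumulative_information(["full", "half"], species_cells, 10)
        assert ci[0] == pytest.approx(0.0)
        assert ci[1] == pytest.approx(0.25)

    def test_single_site_closed_form(self):
        n, m = 17, 40
        species_cells = {f"s{i}": np.array([i % m]) for i in range(n)}
        ci, pct = rc.cumulative_information(list(species_cells), species_cells, m)
        assert ci[-1] == pytest.approx(n * (1 / m) * (1 - 1 / m))
        assert pct[-1] == pytest.approx(100.0)

    def test_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(11)
        m = 30
        species_cells = {
            f"s{i}": np.sort(rng.choice(m, size=rng.integers(1, m), replace=False))
            for i in range(12)
        }
        order = list(species_cells)
        ci, _ = rc.cumulative_information(order, species_cells, m)
        ci_a, _ = rc.cumulative_information(order[:5], species_cells, m)
        ci_b, _ = rc.cumulative_information(order[5:], species_cells, m)
        assert ci[-1] == pytest.approx(ci_a[-1] + ci_b[-1])


class TestCrossingPoint:
    def make_curve(self, taus):
        n = len(taus)
        k = np.arange(1, n + 1)
        return rc.SubsetCurve("ascending", k, 100 * k / n, 100 * k / n, np.asarray(taus, float))

    def test_never_exceeding_returns_none(self):
        assert rc.crossing_point(self.make_curve([0.1, 0.2, 0.3])) is None

    def test_monotone_crossing_at_k3_of_30(self):
        taus = np.concatenate([[0.1, 0.3, 0.6], np.linspace(0.65, 1.0, 27)])
        got = rc.crossing_point(self.make_curve(taus))
        assert got["k"] == 3
        assert got["pct_species"] == pytest.approx(10.0)
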