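"""RATIO binning and coupling-curve fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial import Polynomial

from ratioflux import coupling, synthetic
from ratioflux.errors import FitError, ParameterError


def frame(ratios, values, var="x"):
    return pd.DataFrame({"ratio": ratios, var: values})


class TestBinning:
    def test_bin_means_and_counts(self):
        b = coupling.bin_by_ratio(frame([0.1, 0.1, 0.9], [2.0, 4.0, 10.0]),
                                  "x", n_bins=2)["all"]
        np.testing.assert_allclose(b.bin_means, [3.0, 10.0])
        np.testing.assert_array_equal(b.bin_counts, [2, 1])

    def test_interior_edge_goes_to_right_bin(self):
        b = coupling.bin_by_ratio(frame([0.5], [7.0]), "x", n_bins=2)["all"]
        assert b.bin_counts[1] == 1 and b.bin_counts[0] == 0

    def test_constant_variable_gives_constant_means(self):
        rng = np.random.default_rng(0)
        b = coupling.bin_by_ratio(frame(rng.uniform(0, 1, 500), np.full(500, 3.3)),
                                  "x", n_bins=20)["all"]
        np.testing.assert_allclose(b.bin_means[b.populated], 3.3)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            coupling.bin_by_ratio(frame([0.5], [1.0]), "x", n_bins=1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.001, max_value=0.999), min_size=1, max_size=200),
           st.integers(min_value=2, max_value=50))
    def test_counts_conserve_observations(self, ratios, n_bins):
        b = coupling.bin_by_ratio(frame(ratios, np.ones(len(ratios))), "x", n_bins)["all"]
        assert b.bin_counts.sum() == len(ratios)

    def test_grouped_binning_shares_edges(self, small_kept, small_net):
        _, meta, _ = small_net
        kept = small_kept.merge(meta[["site_id", "group"]], on="site_id")
        bins = coupling.bin_by_ratio(kept, "le", n_bins=50, group_by="group")
        assert len(bins) > 1
        edges = [b.bin_edges for b in bins.values()]
        for e in edges[1:]:
            np.testing.assert_array_equal(e, edges[0])


class TestFitting:
    def test_linear_recovery(self):
        x = (np.arange(40) + 0.5) / 40  # observations at the bin centres
        b = coupling.bin_by_ratio(frame(x, 2 * x + 1), "x", n_bins=40)["all"]
        model = coupling.fit_coupling_curve(b, degree=1)
        np.testing.assert_allclose(model.coefficients, [1.0, 2.0], atol=1e-8)
        assert model.goodness == pytest.approx(1.0)

    def test_polynomial_truth_recovered_at_matching_degree(self):
        truth = Polynomial([0.3, 1.0, -2.0, 0.8])
        x = (np.arange(120) + 0.5) / 120
        b = coupling.bin_by_ratio(frame(x, truth(x)), "x", n_bins=120)["all"]
        model = coupling.fit_coupling_curve(b, degree=3)
        np.testing.assert_allclose(model.coefficients, truth.coef, atol=1e-7)

    def test_random_forest_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 400)
        b = coupling.bin_by_ratio(frame(x, np.sin(3 * x) + rng.normal(0, 0.1, 400)),
                                  "x", n_bins=40)["all"]
        grid = np.linspace(0.1, 0.9, 50)
        m1 = coupling.fit_coupling_curve(b, family="random_forest", seed=9)
        m2 = coupling.fit_coupling_curve(b, family="random_forest", seed=9)
        np.testing.assert_array_equal(m1.predict(grid), m2.predict(grid))

    def test_underdetermined_fit_rejected(self):
        b = coupling.bin_by_ratio(frame([0.1, 0.5, 0.9], [1, 2, 3]), "x", n_bins=3)["all"]
        with pytest.raises(FitError):
            coupling.fit_coupling_curve(b, degree=6)

    def test_unknown_family_rejected(self):
        x = np.linspace(0.05, 0.95, 40)
        b = coupling.bin_by_ratio(frame(x, x), "x", n_bins=10)["all"]
        with pytest.raises(ParameterError):
            coupling.fit_coupling_curve(b, family="spline")


class TestPeak:
    def test_parabola_peak_found(self):
        x = np.linspace(0.3, 1.0, 200)
        b = coupling.bin_by_ratio(frame(x, -((x - 0.94) ** 2)), "x", n_bins=200)["all"]
        model = coupling.fit_coupling_curve(b, degree=2)
        peak, boundary = coupling.peak_location(model)
        assert peak == pytest.approx(0.94, abs=1e-3)
        assert not boundary

    def test_monotone_curve_flags_boundary(self):
        x = np.linspace(0.05, 0.95, 50)
        b = coupling.bin_by_ratio(frame(x, 3 * x), "x", n_bins=50)["all"]
        model = coupling.fit_coupling_curve(b, degree=1)
        peak, boundary = coupling.peak_location(model)
        assert boundary and peak == pytest.approx(model.fit_domain[1])

    def test_nee_uses_argmin(self):
        x = np.linspace(0.3, 1.0, 200)
        b = coupling.bin_by_ratio(frame(x, (x - 0.9) ** 2, var="nee_day"),
                                  "nee_day", n_bins=200)["all"]
        model = coupling.fit_coupling_curve(b, degree=2)
        peak, _ = coupling.peak_location(model)
        assert peak == pytest.approx(0.9, abs=1e-3)

    def test_noiseless_network_recovers_prescribed_peak_exactly(self):
        """With zero noise the binned curve sits on the prescribed coupling."""
        cfg = synthetic.SyntheticConfig(
            n_sites=6, years=(2002, 2003), seed=2,
            noise_sd={v: 0.0 for v in synthetic.DEFAULT_NOISE_SD},
            site_effect_sd={v: 0.0 for v in synthetic.DEFAULT_SITE_EFFECT_SD},
            target_out_of_range_fraction=0.0,
            trends={},
        )
        from ratioflux import pipeline, ratio_core

        summaries, _, truth = pipeline.simulate_summaries(cfg)
        kept, _ = ratio_core.filter_ratio(summaries)
        spec = truth["couplings"]["gpp_day"]
        expected = synthetic.coupling_value(spec, kept["ratio"].to_numpy())
        np.testing.assert_allclose(kept["gpp_day"], expected, rtol=1e-8)
        b = coupling.bin_by_ratio(kept, "gpp_day", n_bins=100)["all"]
        model = coupling.fit_coupling_curve(b)
        peak, _ = coupling.peak_location(model)
        assert abs(peak - spec["peak"]) <= 0.01


class TestDiscrepancy:
    def _binned(self, values, ratios, var="le"):
        return coupling.bin_by_ratio(frame(ratios, values, var=var), var, n_bins=10)["all"]

    def test_identical_groups_have_zero_discrepancy(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, 300)
        v = np.sin(r)
        prof = coupling.between_group_discrepancy(self._binned(v, r), self._binned(v, r))
        np.testing.assert_allclose(prof["abs_diff"], 0.0)

    def test_injected_offset_appears_in_every_bin(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 1, 2000)
        v = np.cos(r)
        prof = coupling.between_group_discrepancy(
            self._binned(v, r), self._binned(v + 0.5, r))
        np.testing.assert_allclose(prof["abs_diff"], 0.5, atol=1e-9)
        assert prof.attrs["mean_below_cutoff"] == pytest.approx(0.5)

    def test_discrepancy_shrinks_with_sample_size(self):
        """Same coupling + independent noise: discrepancy ~ sampling error ~ 1/sqrt(n)."""
        rng = np.random.default_rng(5)

        def group(n):
            r = rng.uniform(0, 1, n)
            return self._binned(np.sin(r) + rng.normal(0, 1.0, n), r)

        small = coupling.between_group_discrepancy(group(60), group(60))
        big = coupling.between_group_discrepancy(group(4000), group(4000))
        assert big["abs_diff"].mean() < 0.5 * small["abs_diff"].mean()

    def test_mismatched_edges_rejected(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0, 1, 100)
        a = self._binned(np.sin(r), r)
        b = coupling.bin_by_ratio(frame(r, np.sin(r), var="le"), "le", n_bins=20)["all"]
        with pytest.raises(ParameterError):
            coupling.between_group_discrepancy(a, b)
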