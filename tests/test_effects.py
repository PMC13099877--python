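import numpy as np
import pandas as pd
import pytest

from dlnmm.basis import CrossBasisSpec
from dlnmm.effects import (
    RRSurface,
    _contrast_matrix,
    cumulative_irr,
    percentile_contrasts,
    rr_surface,
    significant_windows,
)


class FakeResults:
    """Minimal results stub carrying one cross-basis block."""

    def __init__(self, spec, coefs, vcov, series=None):
        self._spec, self._coefs, self._vcov = spec, coefs, vcov
        self.model = type("M", (), {})()
        self.model.design_info = None
        self._series = series

    def crossbasis_block(self, exposure):
        return self._coefs, self._vcov, self._spec


@pytest.fixture()
def random_block(rng):
    x = rng.normal(20.0, 3.0, 500)
    spec = CrossBasisSpec.from_data("temperature", x, max_lag=6)
    q = spec.n_columns
    # scale coefficients to the raw basis columns so log-RR stays O(0.1)
    col_scale = np.repeat(np.abs(spec.exposure_basis(x)).max(axis=0),
                          spec.lag_df_effective) * (spec.max_lag + 1)
    coefs = 0.05 * rng.standard_normal(q) / col_scale
    A = rng.standard_normal((q, q))
    vcov = 1e-4 * (A @ A.T + q * np.eye(q)) / np.outer(col_scale, col_scale)
    return x, spec, coefs, vcov


class TestRRSurface:
    def test_null_coefficients_give_unit_rr(self, random_block):
        x, spec, _, vcov = random_block
        res = FakeResults(spec, np.zeros(spec.n_columns), vcov)
        surf = rr_surface(res, "temperature", reference=20.0, exposure_series=x)
        assert np.allclose(surf.rr, 1.0)
        assert (surf.ci_low <= 1.0 + 1e-12).all()
        assert (surf.ci_high >= 1.0 - 1e-12).all()

    def test_reference_row_is_exactly_one_with_zero_variance(self, random_block):
        x, spec, coefs, vcov = random_block
        res = FakeResults(spec, coefs, vcov)
        ref = 21.3
        surf = rr_surface(res, "temperature", grid=np.array([ref]),
                          reference=ref, exposure_series=x)
        assert np.all(surf.rr == 1.0)
        assert np.all(surf.ci_low == 1.0) and np.all(surf.ci_high == 1.0)

    def test_surface_matches_per_cell_oracle(self, random_block, rng):
        x, spec, coefs, vcov = random_block
        res = FakeResults(spec, coefs, vcov)
        ref = float(x.mean())
        grid = np.linspace(x.min(), x.max(), 7)
        surf = rr_surface(res, "temperature", grid=grid, reference=ref,
                          exposure_series=x)
        H = spec.lag_basis()
        b_ref = spec.exposure_basis([ref])[0]
        for i, xv in enumerate(grid):
            b_x = spec.exposure_basis([xv])[0]
            for l in range(spec.max_lag + 1):
                c = np.outer(b_x - b_ref, H[l]).ravel()
                log_rr = c @ coefs
                var = c @ vcov @ c
                assert np.log(surf.rr[i, l]) == pytest.approx(log_rr, abs=1e-12)
                width = np.log(surf.ci_high[i, l]) - np.log(surf.rr[i, l])
                assert width == pytest.approx(1.959963985 * np.sqrt(var),
                                              rel=1e-9, abs=1e-12)

    def test_coefficient_scaling_scales_log_rr(self, random_block):
        x, spec, coefs, vcov = random_block
        ref = float(x.mean())
        s1 = rr_surface(FakeResults(spec, coefs, vcov), "temperature",
                        reference=ref, exposure_series=x)
        s3 = rr_surface(FakeResults(spec, 3.0 * coefs, vcov), "temperature",
                        reference=ref, exposure_series=x)
        assert np.allclose(np.log(s3.rr), 3.0 * np.log(s1.rr), atol=1e-10)

    def test_ci_width_shrinks_with_vcov(self, random_block):
        x, spec, coefs, vcov = random_block
        ref = float(x.mean())
        wide = rr_surface(FakeResults(spec, coefs, vcov), "temperature",
                          reference=ref, exposure_series=x)
        narrow = rr_surface(FakeResults(spec, coefs, 1e-4 * vcov), "temperature",
                            reference=ref, exposure_series=x)
        w1 = np.log(wide.ci_high) - np.log(wide.ci_low)
        w2 = np.log(narrow.ci_high) - np.log(narrow.ci_low)
        assert (w2 <= w1 + 1e-15).all()

    def test_tidy_frame_shape(self, random_block):
        x, spec, coefs, vcov = random_block
        surf = rr_surface(FakeResults(spec, coefs, vcov), "temperature",
                          n_grid=10, reference=20.0, exposure_series=x)
        df = surf.to_frame()
        assert len(df) == 10 * (spec.max_lag + 1)
        assert {"value", "lag", "rr", "ci_low", "ci_high"} <= set(df.columns)


class TestSignificantWindows:
    @staticmethod
    def surface(rr, lo, hi):
        nx, nl = rr.shape
        return RRSurface("e", np.arange(nx, dtype=float), np.arange(nl),
                         rr, lo, hi, reference=0.0)

    def test_null_surface_yields_empty_list(self):
        rr = np.ones((5, 4))
        s = self.surface(rr, rr * 0.8, rr * 1.2)
        assert significant_windows(s).empty

    def test_single_block_recovered_with_matching_bounds(self):
        rr = np.ones((6, 5))
        lo, hi = rr * 0.8, rr * 1.2
        rr[2:5, 1:4] = 1.5
        lo[2:5, 1:4] = 1.1  # CI excludes 1 in the block
        out = significant_windows(self.surface(rr, lo, hi))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["direction"] == "above 1"
        assert (row["exposure_low"], row["exposure_high"]) == (2.0, 4.0)
        assert (row["lag_low"], row["lag_high"]) == (1, 3)
        assert row["n_cells"] == 9

    def test_direction_flips_under_negation(self):
        rr = np.ones((6, 5))
        lo, hi = rr * 0.8, rr * 1.2
        rr[1:3, 2:4] = 1.4
        lo[1:3, 2:4] = 1.05
        up = significant_windows(self.surface(rr, lo, hi))
        # negate on log scale: rr -> 1/rr, CI swaps and inverts
        down = significant_windows(self.surface(1 / rr, 1 / hi, 1 / lo))
        assert list(up["direction"]) == ["above 1"]
        assert list(down["direction"]) == ["below 1"]
        assert up.iloc[0]["n_cells"] == down.iloc[0]["n_cells"]


class TestCumulativeIRR:
    def test_degenerate_contrast_is_unity(self, random_block):
        x, spec, coefs, vcov = random_block
        res = FakeResults(spec, coefs, vcov)
        cc = cumulative_irr(res, "temperature", 21.0, 21.0)
        assert cc.irr == pytest.approx(1.0)
        assert cc.p_value == pytest.approx(1.0)

    def test_cumulative_equals_sum_of_surface_column(self, random_block):
        x, spec, coefs, vcov = random_block
        res = FakeResults(spec, coefs, vcov)
        target, ref = 24.0, 20.0
        surf = rr_surface(res, "temperature", grid=np.array([target]),
                          reference=ref, exposure_series=x)
        cc = cumulative_irr(res, "temperature", target, ref)
        assert np.log(cc.irr) == pytest.approx(np.log(surf.rr[0]).sum(),
                                               abs=1e-10)

    def test_percentile_contrast_table(self, random_block):
        x, spec, coefs, vcov = random_block
        res = FakeResults(spec, coefs, vcov)
        table = percentile_contrasts(res, "temperature", exposure_series=x)
        assert list(table["contrast"]) == ["p95 vs p50", "p5 vs p50"]
        assert (table["IRR"] > 0).all()
        assert (table["CI_low"] <= table["IRR"]).all()
        assert (table["IRR"] <= table["CI_high"]).all()

    def test_scaling_property(self, random_block):
        x, spec, coefs, vcov = random_block
        c1 = cumulative_irr(FakeResults(spec, coefs, vcov), "temperature",
                            24.0, 20.0)
        c2 = cumulative_irr(FakeResults(spec, 2.0 * coefs, vcov), "temperature",
                            24.0, 20.0)
        assert np.log(c2.irr) == pytest.approx(2 * np.log(c1.irr), abs=1e-10)

    def test_contrast_matrix_column_order_matches_crossbasis(self, rng):
        """The (j, k) flattening must agree with the design column order."""
        from dlnmm.basis import cross_basis

        x = rng.normal(size=100)
        spec = CrossBasisSpec.from_data("e", x, max_lag=4)
        beta = rng.standard_normal((spec.exposure_df, spec.lag_df_effective))
        # predictor difference between two constant series == summed contrast
        cb_hi = cross_basis(np.full(10, 0.8), spec).predictor(beta)
        cb_lo = cross_basis(np.full(10, -0.2), spec).predictor(beta)
        C = _contrast_matrix(spec, [0.8], -0.2)[0].sum(axis=0)
        assert C @ beta.ravel() == pytest.approx(cb_hi[0] - cb_lo[0], abs=1e-10)
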