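import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazelhealth import (
    SubImage,
    VIConfig,
    compute_all,
    compute_vi_map,
    compute_vi_pixel,
    compute_vi_slice,
    separation_report,
)
from hazelhealth.raster_io import VI_NAMES, RasterConfigError
from hazelhealth.vegindex import cohens_d

BAND_VALUES = st.floats(min_value=0.01, max_value=1.0)


def make_sub(bands, mask=None, label=None):
    shape = next(iter(bands.values())).shape
    return SubImage(
        plant_id="p",
        grid_row=0,
        grid_col=0,
        window=(0, shape[0], 0, shape[1]),
        bands={k: np.asarray(v, dtype=float) for k, v in bands.items()},
        mask=np.ones(shape, dtype=bool) if mask is None else mask,
        label=label,
    )


def uniform_sub(g, r, re, n, shape=(4, 4), **kw):
    return make_sub(
        {
            "GREEN": np.full(shape, g),
            "RED": np.full(shape, r),
            "RED_EDGE": np.full(shape, re),
            "NIR": np.full(shape, n),
        },
        **kw,
    )


class TestPixelFormulas:
    @pytest.mark.parametrize(
        "name, g, r, re, n, expected",
        [
            ("NDVI", 0.1, 0.1, 0.3, 0.5, 2 / 3),  # (0.5-0.1)/0.6
            ("NDVI", 0.1, 0.4, 0.3, 0.4, 0.0),  # NIR == RED
            ("NDVI", 0.1, 0.0, 0.3, 0.5, 1.0),  # upper bound
            ("GNDVI", 0.1, 0.06, 0.3, 0.5, 0.4 / 0.6),
            ("GCI", 0.1, 0.06, 0.3, 0.5, 4.0),
            ("NDREI", 0.1, 0.06, 0.5, 0.5, 0.0),  # NIR == RED_EDGE
            ("RECI", 0.1, 0.06, 0.3, 0.5, 0.5 / 0.3 - 1),
            ("NRI", 0.2, 0.2, 0.3, 0.5, 0.0),  # GREEN == RED
            ("GI", 0.2, 0.2, 0.3, 0.5, 1.0),
            ("GI", 0.1, 0.06, 0.3, 0.5, 5 / 3),
            ("SAVI", 0.1, 0.06, 0.3, 0.5, 1.5 * 0.44 / 1.06),
            # TCARI, standard form: 3[(RE-R) - 0.2 (RE-G)(RE/R)]
            ("TCARI", 0.10, 0.06, 0.30, 0.5, 3 * (0.24 - 0.2 * 0.20 * 5.0)),
        ],
    )
    def test_hand_computed_values(self, name, g, r, re, n, expected):
        assert compute_vi_pixel(name, g, r, re, n) == pytest.approx(expected, abs=1e-12)

    def test_tcari_paper_literal_variant(self):
        # 3[(RE-R) - 0.2 (R-G)(RE/R)] at the healthy canopy means
        cfg = VIConfig(tcari_variant="paper_literal")
        got = compute_vi_pixel("TCARI", 0.10, 0.06, 0.30, 0.5, cfg)
        assert got == pytest.approx(3 * (0.24 - 0.2 * (-0.04) * 5.0), abs=1e-12)

    def test_denominator_guard_marks_invalid(self):
        assert np.isnan(compute_vi_pixel("GI", 0.2, 0.0, 0.3, 0.5))
        assert np.isnan(compute_vi_pixel("GCI", 0.0, 0.1, 0.3, 0.5))

    def test_unknown_vi_is_config_error(self):
        with pytest.raises(RasterConfigError, match="unknown vegetation index"):
            compute_vi_pixel("EVI", 0.1, 0.1, 0.1, 0.1)

    @given(g=BAND_VALUES, r=BAND_VALUES, re=BAND_VALUES, n=BAND_VALUES)
    @settings(max_examples=200, deadline=None)
    def test_savi_with_l_zero_equals_ndvi(self, g, r, re, n):
        cfg = VIConfig(L=0.0)
        savi = compute_vi_pixel("SAVI", g, r, re, n, cfg)
        ndvi = compute_vi_pixel("NDVI", g, r, re, n, cfg)
        assert savi == pytest.approx(ndvi, abs=1e-12)

    @given(a=BAND_VALUES, b=BAND_VALUES)
    @settings(max_examples=100, deadline=None)
    def test_normalized_indices_antisymmetric_under_band_swap(self, a, b):
        assert compute_vi_pixel("NDVI", 0.1, b, 0.3, a) == pytest.approx(
            -compute_vi_pixel("NDVI", 0.1, a, 0.3, b), abs=1e-12
        )
        assert compute_vi_pixel("GNDVI", b, 0.1, 0.3, a) == pytest.approx(
            -compute_vi_pixel("GNDVI", a, 0.1, 0.3, b), abs=1e-12
        )
        assert compute_vi_pixel("NDREI", 0.1, 0.1, b, a) == pytest.approx(
            -compute_vi_pixel("NDREI", 0.1, 0.1, a, b), abs=1e-12
        )
        assert compute_vi_pixel("NRI", a, b, 0.3, 0.5) == pytest.approx(
            -compute_vi_pixel("NRI", b, a, 0.3, 0.5), abs=1e-12
        )

    @given(g=BAND_VALUES, r=BAND_VALUES, re=BAND_VALUES, n=BAND_VALUES,
           c=st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_except_savi(self, g, r, re, n, c):
        for vi in ("NDVI", "GNDVI", "GCI", "NDREI", "RECI", "NRI", "GI"):
            v1 = compute_vi_pixel(vi, g, r, re, n)
            v2 = compute_vi_pixel(vi, c * g, c * r, c * re, c * n)
            assert v2 == pytest.approx(v1, rel=1e-9, abs=1e-9)
        # SAVI's additive L breaks scale invariance away from c = 1
        # (except in the degenerate NIR == RED case where SAVI is 0 anyway)
        if abs(c - 1.0) > 0.2 and abs(n - r) > 1e-3:
            s1 = compute_vi_pixel("SAVI", g, r, re, n)
            s2 = compute_vi_pixel("SAVI", c * g, c * r, c * re, c * n)
            assert s2 != pytest.approx(s1, abs=1e-6)


class TestSliceAggregation:
    def test_uniform_slice_mean_is_pixel_value(self):
        sub = uniform_sub(0.1, 0.1, 0.3, 0.5, shape=(5, 7))
        mean, n_valid = compute_vi_slice(sub, "NDVI")
        assert mean == pytest.approx(2 / 3, abs=1e-12)
        assert n_valid == 35

    def test_fully_masked_slice_flagged(self):
        sub = uniform_sub(0.1, 0.1, 0.3, 0.5)
        sub.mask[:] = False
        mean, n_valid = compute_vi_slice(sub, "NDVI")
        assert n_valid == 0 and np.isnan(mean)

    def test_use_mask_false_averages_all_pixels(self):
        sub = uniform_sub(0.1, 0.1, 0.3, 0.5)
        sub.mask[:] = False
        mean, n_valid = compute_vi_slice(sub, "NDVI", VIConfig(use_mask=False))
        assert n_valid == sub.mask.size and mean == pytest.approx(2 / 3)

    def test_checkerboard_mean_equals_average_of_pixel_values(self):
        nir = np.where(np.indices((4, 4)).sum(axis=0) % 2 == 0, 0.5, 0.3)
        sub = make_sub(
            {"GREEN": np.full((4, 4), 0.1), "RED": np.full((4, 4), 0.1),
             "RED_EDGE": np.full((4, 4), 0.3), "NIR": nir}
        )
        mean, _ = compute_vi_slice(sub, "NDVI")
        v1 = (0.5 - 0.1) / 0.6
        v2 = (0.3 - 0.1) / 0.4
        assert mean == pytest.approx((v1 + v2) / 2, abs=1e-12)

    @pytest.mark.parametrize("vi", VI_NAMES)
    def test_slice_mean_matches_per_pixel_loop_oracle(self, vi, rng):
        bands = {b: rng.uniform(0.02, 1.0, (16, 16)) for b in ("GREEN", "RED", "RED_EDGE", "NIR")}
        mask = rng.random((16, 16)) < 0.7
        sub = make_sub(bands, mask=mask)
        mean, n_valid = compute_vi_slice(sub, vi)
        vals = []
        for i in range(16):
            for j in range(16):
                if not mask[i, j]:
                    continue
                v = compute_vi_pixel(
                    vi, bands["GREEN"][i, j], bands["RED"][i, j],
                    bands["RED_EDGE"][i, j], bands["NIR"][i, j],
                )
                if np.isfinite(v):
                    vals.append(v)
        assert n_valid == len(vals)
        assert mean == pytest.approx(np.mean(vals), abs=1e-10)

    def test_compute_all_is_pure_and_respects_ranges(self, rng):
        for _ in range(50):
            bands = {b: rng.uniform(0.0, 1.0, (6, 6)) for b in ("GREEN", "RED", "RED_EDGE", "NIR")}
            sub = make_sub(bands)
            rec = compute_all(sub)
            rec2 = compute_all(make_sub(bands))
            assert rec.means == rec2.means
            for vi in ("NDVI", "GNDVI", "NDREI", "NRI"):
                if np.isfinite(rec.means[vi]):
                    assert -1.0 <= rec.means[vi] <= 1.0
            for vi in ("GCI", "RECI"):
                if np.isfinite(rec.means[vi]):
                    assert rec.means[vi] >= -1.0
            if rec.n_valid["GI"] > 0:
                assert rec.means["GI"] > 0
            assert all(n <= 36 for n in rec.n_valid.values())


class TestSeparationReport:
    @staticmethod
    def _frame(rng, shift=0.0):
        n = 60
        rows = []
        for label in (0, 1):
            for _ in range(n):
                base = {vi.lower(): rng.normal(0.3, 0.1) for vi in VI_NAMES}
                if label == 1:
                    base["gndvi"] -= shift
                rows.append({"slice_id": "s", "plant_id": "p", "grid_row": 0,
                             "grid_col": 0, "label": label, **base})
        return pd.DataFrame(rows)

    def test_identical_distributions_not_selected(self, rng):
        df = self._frame(rng, shift=0.0)
        rep = separation_report(df)
        assert abs(rep.stats.loc["GNDVI", "d"]) < 0.5
        assert "GNDVI" not in rep.selected

    def test_shifted_feature_selected_with_correct_sign(self, rng):
        df = self._frame(rng, shift=0.3)
        rep = separation_report(df)
        assert rep.stats.loc["GNDVI", "selected"]
        assert rep.stats.loc["GNDVI", "d"] > 0  # healthy higher

    def test_single_class_input_rejected(self, rng):
        df = self._frame(rng)
        with pytest.raises(ValueError, match="both classes"):
            separation_report(df[df.label == 0])

    def test_cohens_d_matches_textbook_formula(self, rng):
        x0 = rng.normal(1.0, 0.5, 40)
        x1 = rng.normal(0.2, 0.7, 25)
        pooled = np.sqrt((39 * x0.var(ddof=1) + 24 * x1.var(ddof=1)) / 63)
        assert cohens_d(x0, x1) == pytest.approx((x0.mean() - x1.mean()) / pooled)
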