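import math

import numpy as np
import pandas as pd
import pytest

from twodsil import (
    ArcSpec,
    EndstoppedConfig,
    FilterBankConfig,
    band_90pct,
    complex_responses,
    curvature_tuning_curve,
    render_arc,
    render_bar,
    simple_responses,
)
from twodsil.endstopped import (
    degree_response,
    degree_responses_raw,
    fit_arc_spec,
    saturate,
    sign_responses_raw,
)
from twodsil.stimuli import StimulusImage


@pytest.fixture(scope="module")
def one_scale():
    bank = FilterBankConfig(sizes=(40,), aspect_ratios=(0.7,))
    es = EndstoppedConfig(flank_gains=(1.5,), sign_displacement_fractions=(0.2,))
    return bank, es


class TestDegree:
    def test_blank_image_gives_zero(self, one_scale):
        bank, es = one_scale
        img = StimulusImage(np.zeros((200, 200)))
        s = simple_responses(img, bank)
        c = complex_responses(s)
        assert not degree_responses_raw(s, c, es, 0).any()
        assert np.allclose(degree_response(s, c, es, 0, 0), 0.0)

    def test_scale_out_of_range(self, one_scale):
        bank, es = one_scale
        img = render_bar(40, 0.0, canvas=200)
        s = simple_responses(img, bank)
        c = complex_responses(s)
        with pytest.raises(IndexError):
            degree_responses_raw(s, c, es, 3)

    def test_matched_bar_beats_long_bar(self, one_scale):
        # endstopping: a bar matching the centre cell's length drives the
        # cell harder than one extending into the inhibitory end zones
        bank, es = one_scale
        resp = {}
        for length in (40, 160):
            img = render_bar(length, 0.0, antialias=True)
            s = simple_responses(img, bank)
            c = complex_responses(s)
            resp[length] = degree_responses_raw(s, c, es, 0)[0, 195:205, 195:205].max()
        assert resp[40] > resp[160]

    def test_preferred_arc_radius_within_printed_band(self):
        # the smallest scale responds at >= 90% of max for radius ~8 px
        curve = curvature_tuning_curve(0, np.arange(4, 26, 1.0))
        r8 = float(curve.loc[curve.radius == 8.0, "response"].iloc[0])
        assert r8 >= 0.9


class TestSign:
    def test_zero_input_gives_zero(self, small_bank, small_es):
        img = StimulusImage(np.zeros((150, 150)))
        s = simple_responses(img, small_bank)
        c = complex_responses(s)
        for sign in ("positive", "negative"):
            assert not sign_responses_raw(s, c, small_es, 0, sign).any()

    def test_invalid_sign_token(self, arc_stacks, small_es):
        _, s, c = arc_stacks
        with pytest.raises(ValueError, match="sign"):
            sign_responses_raw(s, c, small_es, 0, "upward")

    def test_needs_45_degree_channels(self, small_es):
        bank = FilterBankConfig(
            orientations=(0.0, math.pi / 3, 2 * math.pi / 3),
            sizes=(40,), aspect_ratios=(0.7,),
        )
        img = render_bar(60, 0.0, canvas=200)
        s = simple_responses(img, bank)
        c = complex_responses(s)
        with pytest.raises(ValueError, match="45"):
            sign_responses_raw(s, c, EndstoppedConfig(flank_gains=(1.5,),
                               sign_displacement_fractions=(0.2,)), 0, "positive")

    @staticmethod
    def _sign_pair_at_apex(img, bank, es):
        s = simple_responses(img, bank)
        c = complex_responses(s)
        win = slice(193, 207)
        pos = sign_responses_raw(s, c, es, 0, "positive")[0, win, win].max()
        neg = sign_responses_raw(s, c, es, 0, "negative")[0, win, win].max()
        return float(pos), float(neg)

    def test_arc_and_mirror_swap_sign_preference(self, one_scale):
        bank, es = one_scale
        # arc bulging upward (circle centre below the apex) vs its mirror
        up = render_arc(ArcSpec(radius=30, arc_center=(199.5, 229.5),
                                angular_extent=math.pi, orientation=-math.pi / 2),
                        antialias=True)
        down = render_arc(ArcSpec(radius=30, arc_center=(199.5, 169.5),
                                  angular_extent=math.pi, orientation=math.pi / 2),
                          antialias=True)
        pos_u, neg_u = self._sign_pair_at_apex(up, bank, es)
        pos_d, neg_d = self._sign_pair_at_apex(down, bank, es)
        assert (pos_u > neg_u) != (pos_d > neg_d)  # mirroring swaps the order
        # mirror antisymmetry: the two stimuli swap the variant responses
        assert pos_u == pytest.approx(neg_d, rel=0.1)
        assert neg_u == pytest.approx(pos_d, rel=0.1)

    def test_straight_bar_drives_both_variants_equally(self, one_scale):
        bank, es = one_scale
        img = render_bar(300, 0.0, antialias=True)
        pos, neg = self._sign_pair_at_apex(img, bank, es)
        assert pos == pytest.approx(neg, rel=0.05)


class TestSaturation:
    def test_monotone_nondecreasing(self):
        x = np.linspace(0, 50, 200)
        y = saturate(x, alpha=0.15, beta=10.0)
        assert (np.diff(y) >= 0).all()
        assert y[0] == pytest.approx(0.0, abs=1e-12)

    def test_contrast_doubling_never_decreases_endstopped(self, one_scale):
        bank, es = one_scale
        img = render_arc(fit_arc_spec(10), antialias=True)
        dim = StimulusImage(img.pixels * 0.5)
        def resp(i):
            s = simple_responses(i, bank)
            c = complex_responses(s)
            return degree_response(s, c, es, 0, 0, beta=0.1)
        assert (resp(img) >= resp(dim) - 1e-12).all()


class TestTuningCurve:
    def test_single_radius_normalizes_to_one(self):
        curve = curvature_tuning_curve(0, [8.0])
        assert len(curve) == 1
        assert curve.response.iloc[0] == pytest.approx(1.0)

    def test_empty_radii_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            curvature_tuning_curve(0, [])

    def test_small_scale_prefers_sharper_arcs_than_large(self):
        c_small = curvature_tuning_curve(0, np.arange(4, 26, 2.0))
        c_large = curvature_tuning_curve(3, np.arange(60, 361, 25.0))
        r_small = c_small.radius[c_small.response.idxmax()]
        r_large = c_large.radius[c_large.response.idxmax()]
        assert r_small < r_large

    def test_smallest_scale_curve_unimodal(self):
        curve = curvature_tuning_curve(0, np.arange(4, 41, 2.0))
        v = np.convolve(curve.response, np.ones(3) / 3, mode="valid")
        interior_maxima = [
            i for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1]
        ]
        # ripple bumps must not protrude more than 5% of the peak
        for i in interior_maxima:
            trailing_min = v[i:].min()
            assert v[i] - trailing_min <= 0.05 or v[i] == v.max()


class TestBand90:
    def test_single_point_band(self):
        curve = pd.DataFrame({"radius": [12.0], "response": [0.7]})
        assert band_90pct(curve) == (12.0, 12.0)

    def test_triangular_curve_matches_brute_force(self):
        r = np.arange(0, 21, dtype=float)
        v = 1.0 - np.abs(r - 10) / 10.0
        band = band_90pct(pd.DataFrame({"radius": r, "response": v}))
        # brute-force scan on a dense grid
        rr = np.linspace(0, 20, 20001)
        vv = np.interp(rr, r, v)
        keep = rr[vv >= 0.9 * vv.max()]
        assert band[0] == pytest.approx(keep.min(), abs=1e-3)
        assert band[1] == pytest.approx(keep.max(), abs=1e-3)

    def test_all_zero_curve_rejected(self):
        curve = pd.DataFrame({"radius": [1.0, 2.0], "response": [0.0, 0.0]})
        with pytest.raises(ValueError):
            band_90pct(curve)
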