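"""Attention peak, window averaging and the 2-D feature mapping."""

import numpy as np
import pytest

from ieamsc import (
    AttentionPoint,
    EmptyBandError,
    FilterThresholds,
    MappingConfig,
    RunConfig,
    apply_filter,
    attention_peak,
    compute_energy,
    find_thresholds,
    map_point,
    process_image,
)

from conftest import make_spectrum

T = FilterThresholds(T1=50, T2=200)


def peak_oracle(counts, t, n):
    """Independent oracle: explicit scans over the open band and window."""
    band = range(t.T1 + 1, t.T2)
    h_star = max(band, key=lambda h: (counts[h], -h))  # first maximum
    lo = max(h_star - n, t.T1 + 1)
    hi = min(h_star + n, t.T2 - 1)
    window = [counts[h] for h in range(lo, hi + 1)]
    return h_star, sum(window) / len(window)


def test_zero_width_window_is_peak_count():
    s = make_spectrum(R={100: 500})
    a = attention_peak(s, T, "R", n=0)
    assert (a.h_star, a.n_ave) == (100, 500.0)


def test_window_average_by_hand():
    s = make_spectrum(R={99: 100, 100: 500, 101: 300})
    a = attention_peak(s, T, "R", n=1)
    assert a.h_star == 100
    assert a.n_ave == pytest.approx((100 + 500 + 300) / 3)


def test_window_clipped_at_band_edge():
    # peak at T1+1: only bins T1+1..T1+3 exist in the window
    counts = {51: 900, 52: 10, 53: 20, 54: 5}
    s = make_spectrum(R=counts)
    a = attention_peak(s, T, "R", n=2)
    assert a.h_star == 51
    assert a.n_ave == pytest.approx((900 + 10 + 20) / 3)


def test_strict_division_keeps_full_denominator():
    s = make_spectrum(R={51: 900, 52: 10, 53: 20})
    a = attention_peak(s, T, "R", n=2, window_mode="strict")
    assert a.n_ave == pytest.approx((900 + 10 + 20) / 5)


def test_argmax_tie_breaks_to_smallest():
    s = make_spectrum(G={120: 400, 160: 400})
    assert attention_peak(s, T, "G", n=0).h_star == 120


def test_random_band_matches_oracle(rng):
    counts = {h: int(c) for h, c in enumerate(rng.integers(0, 1000, 256))}
    s = make_spectrum(B=counts)
    for n in (0, 1, 2, 5):
        a = attention_peak(s, T, "B", n=n)
        h_star, n_ave = peak_oracle(s.counts_B, T, n)
        assert a.h_star == h_star
        assert a.n_ave == pytest.approx(n_ave)


def test_window_average_bounded_by_window_max(rng):
    counts = {h: int(c) for h, c in enumerate(rng.integers(0, 1000, 256))}
    s = make_spectrum(R=counts)
    a = attention_peak(s, T, "R", n=3)
    assert a.n_ave <= s.counts_R[a.h_star]  # peak is the window max


def test_flat_window_average_equals_count():
    # plateau at the band edge: ties put h* at 51, the window clips to
    # [51, 53], and the average of equal bins is the bin count itself
    s = make_spectrum(R={h: 200 for h in range(51, 56)})
    a = attention_peak(s, T, "R", n=2)
    assert a.h_star == 51
    assert a.n_ave == 200.0


def test_empty_band_rejected():
    s = make_spectrum(R={220: 50})  # energy only outside the band
    with pytest.raises(EmptyBandError, match="no tea energy"):
        attention_peak(s, T, "R", n=2)


# -- mapping -------------------------------------------------------------


def test_zero_energy_maps_to_top():
    p = map_point(AttentionPoint("R", 100, 0.0), MappingConfig())
    assert (p.x, p.y) == (100, 800)


def test_full_scale_mapping():
    p = map_point(AttentionPoint("R", 100, 25000.0), MappingConfig())
    assert p.y == 800 - 700


def test_reference_round_trip():
    # a mapped y of 271 corresponds to a window average of (800-271)*25000/700
    n_ave = (800 - 271) * 25000 / 700
    p = map_point(AttentionPoint("R", 70, n_ave), MappingConfig())
    assert p.y == 271


def test_y_clamped_at_zero():
    p = map_point(AttentionPoint("R", 70, 1e9), MappingConfig())
    assert p.y == 0


def test_floor_mode_differs_by_at_most_one():
    a = AttentionPoint("G", 90, 18892.9)
    y_round = map_point(a, MappingConfig(int_mode="round")).y
    y_floor = map_point(a, MappingConfig(int_mode="floor")).y
    assert 0 <= y_round - y_floor <= 1


def test_y_monotone_in_energy():
    cfg = MappingConfig()
    ys = [map_point(AttentionPoint("R", 70, v), cfg).y for v in np.linspace(0, 30000, 50)]
    assert all(a >= b for a, b in zip(ys, ys[1:]))


def test_axis_scales_applied():
    cfg = RunConfig(x_scale=0.01, y_scale=0.001)
    a = AttentionPoint("R", 70, 0.0)
    p = map_point(a, cfg.mapping, cfg.x_scale, cfg.y_scale)
    assert p.x == pytest.approx(0.70)
    assert p.y == pytest.approx(0.8)


# -- per-image pipeline --------------------------------------------------


def test_process_image_composes_stages(tea_image):
    cfg = RunConfig()
    triple = process_image(tea_image, cfg)
    spectrum = compute_energy(tea_image)
    t = find_thresholds(spectrum)
    filtered = apply_filter(spectrum, t)
    assert triple.thresholds == t
    for ch in "RGB":
        a = attention_peak(filtered, t, ch, n=cfg.mapping.n)
        expected = map_point(a, cfg.mapping)
        assert triple.point(ch) == expected


@pytest.mark.parametrize("k", [1, 2, 3])
def test_process_image_rotation_invariant(tea_image, k):
    base = process_image(tea_image)
    rotated = process_image(np.ascontiguousarray(np.rot90(tea_image, k)))
    for ch in "RGB":
        assert base.point(ch) == rotated.point(ch)


def test_process_image_attaches_image_id_to_errors():
    white = np.full((8, 8, 3), 255, dtype=np.uint8)
    with pytest.raises(Exception, match="frame-7"):
        process_image(white, image_id="frame-7")
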