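"""Filtering, referencing, interpolation, epoching, rejection, baseline."""

import numpy as np
import pytest
from scipy import signal

from cortrack.errors import (
    BadBand,
    EmptyWindow,
    IslandChannel,
    MissingChannel,
    NoEvents,
)
from cortrack.io import Recording
from cortrack.montage import Montage
from cortrack.preprocess import (
    EpochSet,
    baseline_correct,
    design_bandpass,
    drop_channels,
    epoch_by_events,
    fir_bandpass,
    interpolate_channels,
    reject_epochs,
    rereference,
)

FS = 500.0


def make_rec(data, events=(), fs=FS, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(fs_hz=fs, channel_labels=labels, data=data, events=list(events))


# -- FIR band-pass -----------------------------------------------------


def test_bandpass_passes_tagged_rate():
    t = np.arange(int(90 * FS)) / FS
    rec = make_rec(np.sin(2 * np.pi * 3.125 * t))
    out = fir_bandpass(rec, 0.1, 25.0)
    mid = slice(int(40 * FS), int(50 * FS))  # steady state, edges trimmed
    amp = np.abs(signal.hilbert(out.data[0, mid])).mean()
    assert 0.99 <= amp <= 1.01


def test_bandpass_removes_dc():
    rec = make_rec(np.full(int(90 * FS), 10.0))
    out = fir_bandpass(rec, 0.1, 25.0)
    mid = slice(int(40 * FS), int(50 * FS))
    assert abs(out.data[0, mid].mean()) < 0.5


def test_bandpass_stopband_attenuation():
    h = design_bandpass(0.1, 25.0, FS)
    h2 = np.convolve(h, h)  # effective forward-backward response
    for f_eval in (0.05, 50.0):
        w, H = signal.freqz(h2, worN=[f_eval], fs=FS)
        assert 20 * np.log10(np.abs(H[0])) <= -40.0


def test_bandpass_is_linear(rng):
    x = rng.standard_normal((2, 8000))
    y = rng.standard_normal((2, 8000))
    a, b = 2.5, -1.3
    fa = fir_bandpass(make_rec(x), 1.0, 30.0).data
    fb = fir_bandpass(make_rec(y), 1.0, 30.0).data
    fab = fir_bandpass(make_rec(a * x + b * y), 1.0, 30.0).data
    assert np.allclose(fab, a * fa + b * fb, atol=1e-9)


@pytest.mark.parametrize("lo, hi", [(0.0, 25.0), (25.0, 0.1), (0.1, 300.0)])
def test_bandpass_bad_band(lo, hi):
    with pytest.raises(BadBand):
        fir_bandpass(make_rec(np.zeros(100)), lo, hi)


# -- re-referencing ----------------------------------------------------


def test_common_average_zeroes_channel_mean(rng):
    rec = make_rec(rng.standard_normal((8, 1000)))
    out = rereference(rec, "common_average")
    assert np.abs(out.data.mean(axis=0)).max() < 1e-10


def test_linked_mastoids_two_channel_algebra(rng):
    x = rng.standard_normal(500)
    y = rng.standard_normal(500)
    rec = make_rec(np.stack([x, y]), labels=["M1", "M2"])
    out = rereference(rec, "linked_mastoids")
    assert np.allclose(out.data[0], (x - y) / 2)
    assert np.allclose(out.data[1], (y - x) / 2)


def test_linked_mastoids_missing_channel():
    rec = make_rec(np.zeros((2, 10)), labels=["A", "B"])
    with pytest.raises(MissingChannel):
        rereference(rec, "linked_mastoids")


def test_drop_channels_strict():
    rec = make_rec(np.zeros((2, 10)), labels=["A", "B"])
    assert drop_channels(rec, ["B"]).channel_labels == ["A"]
    with pytest.raises(MissingChannel):
        drop_channels(rec, ["C"], strict=True)


# -- interpolation -----------------------------------------------------


def test_interpolate_identical_neighbors(montage64, rng):
    s = rng.standard_normal(300)
    rec = Recording(
        fs_hz=FS,
        channel_labels=list(montage64.labels),
        data=np.tile(s, (montage64.n_channels, 1)),
    )
    rec.data[montage64.index("Cz")] = 999.0
    out = interpolate_channels(rec, ["Cz"], montage64)
    assert np.allclose(out.data[montage64.index("Cz")], s)


def test_interpolate_equilateral_center_is_plain_mean(rng):
    # center channel equidistant from three corners -> unweighted mean
    pos = np.array([[0.0, 1.0], [-np.sqrt(3) / 2, -0.5], [np.sqrt(3) / 2, -0.5],
                    [0.0, 0.0]])
    m = Montage(labels=["A", "B", "C", "X"], pos=pos,
                gain_osc=np.ones(4), gain_erp=np.ones(4), roi=[])
    data = rng.standard_normal((4, 200))
    rec = Recording(fs_hz=FS, channel_labels=m.labels, data=data.copy())
    out = interpolate_channels(rec, ["X"], m)
    assert np.allclose(out.data[3], data[:3].mean(axis=0))


def test_interpolate_island(montage64, rng):
    rec = Recording(
        fs_hz=FS,
        channel_labels=list(montage64.labels),
        data=rng.standard_normal((montage64.n_channels, 50)),
    )
    with pytest.raises(IslandChannel):
        interpolate_channels(rec, list(montage64.labels), montage64)


# -- epoching ----------------------------------------------------------


def test_epoch_sample_counts():
    rec = make_rec(np.zeros((2, 5000)), events=[(1000, "word"), (3000, "word")])
    es = epoch_by_events(rec, "word", -0.1, 0.7)
    assert es.data.shape == (2, 2, 400)
    assert es.t0_offset_s == -0.1


def test_epoch_entrainment_length(spec, rng):
    n = int(16 * FS)
    rec = make_rec(rng.standard_normal((1, n)), events=[(100, "trial")])
    es = epoch_by_events(rec, "trial", 1.28, 15.36)
    assert es.n_samples == 7040


def test_epoch_boundary_dropped_with_warning(caplog):
    rec = make_rec(np.zeros((1, 1000)), events=[(10, "w"), (500, "w")])
    with caplog.at_level("WARNING", logger="cortrack.preprocess"):
        es = epoch_by_events(rec, "w", -0.1, 0.7)
    assert es.n_epochs == 1
    assert es.metadata["dropped_boundary"] == 1
    assert any("overrunning" in r.message for r in caplog.records)


def test_epoch_no_events():
    rec = make_rec(np.zeros((1, 100)), events=[(50, "other")])
    with pytest.raises(NoEvents):
        epoch_by_events(rec, "word", -0.1, 0.1)


# -- rejection ---------------------------------------------------------


def _epochs(data, conds=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(
        data=data, fs_hz=FS, t0_offset_s=-0.1,
        conditions=conds or ["c"] * n,
        retained=np.ones(n, dtype=bool),
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
    )


def test_reject_single_spike():
    data = np.zeros((2, 1, 400))
    data[0, 0, 123] = 80.0
    data[1] = 74.0
    es, frac = reject_epochs(_epochs(data), 75.0)
    assert list(es.retained) == [False, True]
    assert frac == 0.5


def test_reject_idempotent_and_order_free(rng):
    data = rng.standard_normal((10, 3, 100)) * 40
    es1, _ = reject_epochs(_epochs(data), 75.0)
    es2, frac2 = reject_epochs(es1, 75.0)
    assert np.array_equal(es1.retained, es2.retained) and frac2 == 0.0
    perm = rng.permutation(10)
    esp, _ = reject_epochs(_epochs(data[perm]), 75.0)
    assert np.array_equal(esp.retained, es1.retained[perm])


# -- baseline ----------------------------------------------------------


def test_baseline_zeroes_window_mean(rng):
    data = rng.standard_normal((5, 4, 400)) + 3.0
    es = baseline_correct(_epochs(data), -0.1, 0.0)
    assert np.abs(es.data[:, :, :50].mean(axis=2)).max() < 1e-10


def test_baseline_constant_epoch_becomes_zero():
    es = baseline_correct(_epochs(np.full((1, 2, 400), 5.0)), -0.1, 0.0)
    assert np.allclose(es.data, 0.0)


def test_baseline_ramp_zero_at_window_mean_time():
    # linear ramp: corrected value vanishes at the mean time of the
    # (half-open) baseline window's samples
    t = -0.1 + np.arange(400) / FS
    slope = 7.0
    es = baseline_correct(_epochs((slope * t)[None, None, :]), -0.1, 0.0)
    t_mean = t[:50].mean()
    expect = slope * (t - t_mean)
    assert np.allclose(es.data[0, 0], expect, atol=1e-12)


def test_baseline_empty_window():
    with pytest.raises(EmptyWindow):
        baseline_correct(_epochs(np.zeros((1, 1, 400))), 0.9, 1.0)
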