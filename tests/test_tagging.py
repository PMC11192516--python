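"""Evoked power, neighbor normalization and the peak-vs-neighbors test."""

import numpy as np
import pytest

from cortrack import paradigm as par
from cortrack.errors import LengthMismatch, NoRetainedEpochs, UndefinedBin
from cortrack.pipeline import entrainment_subject_pairs
from cortrack.preprocess import EpochSet
from cortrack.tagging import (
    evoked_average,
    evoked_power,
    group_peak_test,
    neighbor_normalize,
    subject_peak_pair,
)

FS = 500.0
N = 7040  # default 14.08 s epoch at 500 Hz


def _epochs(data):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(
        data=data, fs_hz=FS, t0_offset_s=0.0,
        conditions=["trial"] * n,
        retained=np.ones(n, dtype=bool),
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
    )


def brute_force_power(x, n):
    """O(N^2) one-sided DFT power oracle with the same scaling convention."""
    k = np.arange(n // 2 + 1)
    W = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    X = W @ x
    amp = 2 * np.abs(X) / n
    amp[0] /= 2
    if n % 2 == 0:
        amp[-1] /= 2
    return amp**2


# -- evoked average ----------------------------------------------------


def test_average_single_epoch_is_itself(rng):
    x = rng.standard_normal((1, 2, 64))
    assert np.array_equal(evoked_average(_epochs(x)), x[0])


def test_average_of_opposite_epochs_is_zero(rng):
    x = rng.standard_normal((2, 64))
    assert np.allclose(evoked_average(_epochs(np.stack([x, -x]))), 0.0)


def test_average_requires_retained_epochs(rng):
    es = _epochs(rng.standard_normal((2, 1, 8)))
    es.retained[:] = False
    with pytest.raises(NoRetainedEpochs):
        evoked_average(es)


def test_average_noise_shrinks_as_sqrt_n(rng):
    t = np.arange(512) / FS
    template = np.sin(2 * np.pi * 5 * t)
    rms = {}
    for n in (4, 16, 64):
        resid = []
        for _ in range(40):
            epochs = template + rng.standard_normal((n, 512))
            avg = evoked_average(_epochs(epochs[:, None, :]))
            resid.append(np.sqrt(((avg[0] - template) ** 2).mean()))
        rms[n] = np.mean(resid)
    assert rms[4] / rms[16] == pytest.approx(2.0, rel=0.2)
    assert rms[16] / rms[64] == pytest.approx(2.0, rel=0.2)


# -- evoked power ------------------------------------------------------


def test_unit_sinusoid_power_at_its_bin():
    t = np.arange(N) / FS
    ss = evoked_power(np.sin(2 * np.pi * 3.125 * t), FS)
    p = 10 ** (ss.power_db[0] / 10)
    assert p[44] == pytest.approx(1.0, rel=1e-9)
    mask = np.ones(p.size, dtype=bool)
    mask[[0, 44]] = False
    assert p[mask].max() < 1e-12


def test_amplitude_two_is_plus_six_db():
    t = np.arange(N) / FS
    ss = evoked_power(2.0 * np.sin(2 * np.pi * 3.125 * t), FS)
    assert ss.power_db[0, 44] == pytest.approx(10 * np.log10(4), abs=1e-9)


def test_power_matches_brute_force_dft(rng):
    for n in (128, 250, 391):
        x = rng.standard_normal(n)
        ss = evoked_power(x, FS)
        p = 10 ** (ss.power_db[0] / 10)
        expect = brute_force_power(x, n)
        assert np.allclose(p, expect, rtol=1e-9, atol=1e-15)


def test_power_parseval(rng):
    x = rng.standard_normal(1024)
    p = 10 ** (evoked_power(x, FS).power_db[0] / 10)
    two_sided = p[0] + p[1:-1].sum() / 2 + p[-1]
    assert two_sided == pytest.approx((x**2).mean(), rel=1e-9)


def test_power_length_check(rng):
    with pytest.raises(LengthMismatch):
        evoked_power(rng.standard_normal(100), FS, expected_len=7040)


# -- neighbor normalization -------------------------------------------


def test_flat_spectrum_normalizes_to_zero():
    ss = evoked_power(np.zeros(256) + 0.0, FS)
    ss.power_db = np.full_like(ss.power_db, 7.0)  # flat floor in dB
    out = neighbor_normalize(ss, 2)
    defined = ~np.isnan(out.normalized_db[0])
    assert np.allclose(out.normalized_db[0, defined], 0.0)
    assert not defined[:3].any() and not defined[-2:].any()


def test_single_bin_peak_normalization():
    ss = evoked_power(np.zeros(256), FS)
    ss.power_db = np.zeros_like(ss.power_db)
    ss.power_db[0, 40] = 10.0
    out = neighbor_normalize(ss, 2)
    assert out.normalized_db[0, 40] == pytest.approx(10.0)
    assert out.normalized_db[0, 39] == pytest.approx(-2.5)
    assert out.normalized_db[0, 41] == pytest.approx(-2.5)


def test_white_noise_normalizes_to_zero_mean(rng):
    # 300 white-noise subjects, 32 electrodes each; the electrode-averaged
    # normalized value at the syllabic bin has expectation exactly 0
    vals = []
    for _ in range(300):
        x = rng.standard_normal((32, N))
        ss = evoked_power(x, FS)
        peak, neigh = subject_peak_pair(ss, 44)
        vals.append(peak - neigh)
    assert abs(np.mean(vals)) < 0.2


# -- subject aggregation ----------------------------------------------


def test_peak_pair_uniform_electrodes_match_single(rng):
    x = rng.standard_normal(512)
    one = evoked_power(x, FS)
    three = evoked_power(np.tile(x, (3, 1)), FS)
    assert subject_peak_pair(one, 20) == pytest.approx(subject_peak_pair(three, 20))


def test_peak_pair_mean_over_electrodes():
    ss = evoked_power(np.zeros((2, 256)), FS)
    ss.power_db = np.zeros_like(ss.power_db)
    ss.power_db[0, 30] = 4.0
    ss.power_db[1, 30] = 6.0
    peak, neigh = subject_peak_pair(ss, 30)
    assert peak == pytest.approx(5.0) and neigh == pytest.approx(0.0)


def test_peak_pair_undefined_bin():
    ss = evoked_power(np.zeros(64), FS)
    with pytest.raises(UndefinedBin):
        subject_peak_pair(ss, 2)
    with pytest.raises(UndefinedBin):
        subject_peak_pair(ss, 44, electrodes=["nope"])


# -- group test --------------------------------------------------------


def test_group_peak_test_closed_form():
    pairs = [(2, 1), (3, 1), (4, 1)]
    res = group_peak_test(pairs)
    assert res.t_statistic == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-6)
    assert res.df == 2
    assert res.p_one_tailed == pytest.approx(0.0371, abs=5e-4)


def test_group_peak_test_all_zero_differences():
    res = group_peak_test([(1.0, 1.0)] * 5)
    assert res.t_statistic == 0.0 and res.p_one_tailed == 0.5


def test_group_peak_test_constant_positive_difference():
    res = group_peak_test([(2.0, 1.0)] * 5)
    assert res.p_one_tailed == 0.0 and res.significant


# -- end-to-end oracles ------------------------------------------------


def _subject(**kw):
    from cortrack.synth import SubjectParams

    base = dict(
        subject_id="S", group="NL",
        amp_sentential=0.5, amp_phrasal=0.0, amp_syllabic=0.0,
        phase_sentential=0.7, phase_phrasal=0.0, phase_syllabic=0.0,
        n400_effect=-1.0, n400_latency_ms=400.0, noise_scale=10.0,
        artifact_rate=0.0, seed=5,
    )
    base.update(kw)
    return SubjectParams(**base)


def _epoch_power_pairs(sp, spec, m):
    """Simulate -> epoch -> average -> power, without filter/reference."""
    from cortrack.preprocess import epoch_by_events
    from cortrack.synth import simulate_entrainment

    rec = simulate_entrainment(sp, spec, m, dtype=np.float64)
    sent = par.sentence_duration(spec)
    es = epoch_by_events(rec, "trial", sent, spec.sentences_per_trial * sent)
    ss = evoked_power(evoked_average(es), spec.fs_hz,
                      channel_labels=es.channel_labels)
    return {r: subject_peak_pair(ss, b) for r, b in par.tag_bins(spec).items()}


def test_noise_off_normalized_peak_hits_machine_floor(spec, montage64):
    m = montage64.subset(["C3", "Cz", "C4"])
    pairs = _epoch_power_pairs(
        _subject(amp_sentential=1.0, noise_scale=1e-12), spec, m
    )
    peak, neigh = pairs["sentential"]
    assert peak - neigh > 100.0  # floor set by machine precision


def test_sentential_response_monotone_in_amplitude(spec, montage64):
    m = montage64.subset(["Cz", "C3", "CP3", "P5", "AF3", "Oz"])
    diffs = []
    for amp in (0.3, 0.8, 2.0):
        pairs = _epoch_power_pairs(
            _subject(amp_sentential=amp, noise_scale=5.0, seed=31), spec, m
        )
        peak, neigh = pairs["sentential"]
        diffs.append(peak - neigh)
    assert diffs[0] < diffs[1] < diffs[2]


def test_full_pipeline_recovers_strong_peaks(spec, montage64):
    # filter + common-average + epoch + power on a high-SNR subject:
    # every tagged rate stands far above its neighbor bins
    m = montage64.subset(["Cz", "C3", "CP3", "P5", "AF3", "Oz"])
    pairs = entrainment_subject_pairs(
        _subject(amp_sentential=1.0, amp_phrasal=1.0, amp_syllabic=1.0,
                 noise_scale=1.0, seed=7),
        spec, m,
    )
    for rate, (peak, neigh) in pairs.items():
        assert peak - neigh > 10.0, rate
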