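"""Generator ground truth: copula coupling, noise spectrum, templates."""

import numpy as np
import pytest
import scipy.stats as sps

from cortrack.errors import DegenerateDistribution
from cortrack.montage import standard_64
from cortrack.preprocess import baseline_correct, epoch_by_events, reject_epochs
from cortrack.synth import (
    CohortSpec,
    SubjectParams,
    draw_cohort,
    inject_artifacts,
    pink_noise,
    simulate_entrainment,
    simulate_n400,
)


def make_subject(**kw) -> SubjectParams:
    base = dict(
        subject_id="S01", group="NL",
        amp_sentential=0.8, amp_phrasal=1.0, amp_syllabic=1.5,
        phase_sentential=0.3, phase_phrasal=1.1, phase_syllabic=2.2,
        n400_effect=-1.0, n400_latency_ms=400.0, noise_scale=10.0,
        artifact_rate=0.0, seed=99,
    )
    base.update(kw)
    return SubjectParams(**base)


# -- cohort draws ------------------------------------------------------


def test_draw_cohort_deterministic():
    cs = CohortSpec(master_seed=42)
    assert draw_cohort(cs) == draw_cohort(cs)


def test_draw_cohort_negative_sd_rejected():
    cs = CohortSpec(master_seed=1)
    cs.distributions["noise_scale"] = (10.0, -1.0)
    with pytest.raises(DegenerateDistribution):
        draw_cohort(cs)


def test_comonotone_coupling_perfectly_coranked():
    sub = draw_cohort(CohortSpec(coupling_rho=1.0, n_subjects=50, master_seed=3))
    amp = np.array([s.amp_sentential for s in sub])
    mag = np.array([abs(s.n400_effect) for s in sub])
    assert sps.spearmanr(amp, mag).statistic == pytest.approx(1.0)


def test_null_coupling_near_zero():
    sub = draw_cohort(CohortSpec(coupling_rho=0.0, n_subjects=1000, master_seed=3))
    amp = [s.amp_sentential for s in sub]
    mag = [abs(s.n400_effect) for s in sub]
    assert abs(sps.spearmanr(amp, mag).statistic) < 0.07


def test_marginals_respect_bounds():
    sub = draw_cohort(CohortSpec(n_subjects=200, master_seed=11))
    for s in sub:
        assert s.amp_sentential >= 0 and s.noise_scale > 0
        assert 0 <= s.comprehension_rating <= 4
        assert 0 <= s.question_accuracy <= 1 and 0 <= s.listening_score <= 1


# -- pink noise --------------------------------------------------------


def test_pink_noise_rms_and_slope(rng):
    x = pink_noise(rng, (120, 4000), 500.0, 10.0)
    assert np.sqrt((x**2).mean()) == pytest.approx(10.0, rel=0.05)
    f = np.fft.rfftfreq(4000, 1 / 500.0)
    P = (np.abs(np.fft.rfft(x, axis=1)) ** 2).mean(axis=0)
    sel = (f >= 0.5) & (f <= 20.0)
    slope = np.polyfit(np.log10(f[sel]), np.log10(P[sel]), 1)[0]
    assert -1.3 < slope < -0.7


# -- entrainment recording --------------------------------------------


def test_noise_free_trial_spectrum_only_tagged_bins(spec, montage64):
    sp = make_subject(noise_scale=1e-12)
    rec = simulate_entrainment(sp, spec, montage64, dtype=np.float64)
    onset = rec.events[0][0]
    n = int(round(spec.sentences_per_trial * 1.28 * spec.fs_hz))
    ch = montage64.index("Cz")
    X = np.abs(np.fft.rfft(rec.data[ch, onset : onset + n]))
    # bins of the full 15.36 s trial: the tagged rates complete 12/24/48 cycles
    tagged = {12, 24, 48}
    mask = np.ones(X.size, dtype=bool)
    mask[list(tagged)] = False
    mask[0] = False
    assert X[mask].max() <= 1e-9 * X[~mask].max()


def test_noise_free_average_is_pure_sinusoid(spec, montage64):
    sp = make_subject(amp_sentential=0.0, amp_phrasal=0.0, amp_syllabic=1.0,
                      noise_scale=1e-12)
    rec = simulate_entrainment(sp, spec, montage64, dtype=np.float64)
    onsets = [s for s, lb in rec.events if lb == "trial"]
    n = int(round(spec.sentences_per_trial * 1.28 * spec.fs_hz))
    trials = np.stack([rec.data[:, o : o + n] for o in onsets])
    avg = trials.mean(axis=0)
    ch = montage64.index("Cz")
    t = np.arange(n) / spec.fs_hz
    expect = montage64.gain_osc[ch] * np.sin(2 * np.pi * 3.125 * t + sp.phase_syllabic)
    assert np.allclose(avg[ch], expect, atol=1e-8)


def test_entrainment_event_layout(spec, montage64):
    rec = simulate_entrainment(make_subject(), spec, montage64)
    trials = [s for s, lb in rec.events if lb == "trial"]
    sentences = [s for s, lb in rec.events if lb == "sentence"]
    assert len(trials) == spec.n_trials
    assert len(sentences) == spec.n_trials * spec.sentences_per_trial


# -- N400 recording ----------------------------------------------------


def _measured_effect(rec, roi, window_ms=(300.0, 700.0)):
    es = epoch_by_events(rec, ("congruent", "incongruent"), -0.1, 0.7)
    es = baseline_correct(es, -0.1, 0.0)
    cond = np.asarray(es.conditions)
    roi_idx = [es.channel_labels.index(lb) for lb in roi]
    fs = es.fs_hz
    i0 = int(round((window_ms[0] / 1000 + 0.1) * fs))
    i1 = int(round((window_ms[1] / 1000 + 0.1) * fs))
    means = {
        c: es.data[cond == c][:, roi_idx, i0:i1].mean() for c in
        ("congruent", "incongruent")
    }
    return means["incongruent"] - means["congruent"]


def test_n400_zero_effect_gives_identical_erps(montage64):
    sp = make_subject(n400_effect=0.0, noise_scale=1e-12)
    rec = simulate_n400(sp, 10, montage64, dtype=np.float64)
    assert abs(_measured_effect(rec, montage64.roi)) < 1e-9


def test_n400_noise_free_recovery_within_two_percent(montage64):
    sp = make_subject(n400_effect=-1.0, noise_scale=1e-12)
    rec = simulate_n400(sp, 10, montage64, dtype=np.float64)
    eff = _measured_effect(rec, montage64.roi)
    assert eff == pytest.approx(-1.0, rel=0.02)


def test_n400_schedule_fixed_under_schedule_seed(montage64):
    a = simulate_n400(make_subject(seed=1), 8, montage64, schedule_seed=77)
    b = simulate_n400(make_subject(seed=2), 8, montage64, schedule_seed=77)
    assert a.events == b.events
    assert not np.allclose(a.data, b.data)


# -- artifacts ---------------------------------------------------------


def test_artifact_rate_zero_is_identity(montage64):
    sp = make_subject(artifact_rate=0.0)
    rec = simulate_n400(sp, 5, montage64)
    out = inject_artifacts(rec, sp)
    assert np.array_equal(out.data, rec.data)
    assert out.metadata["artifact_events"] == []


def test_artifact_rate_one_rejects_everything(montage64):
    sp = make_subject(artifact_rate=1.0)
    rec = simulate_n400(sp, 5, montage64)
    out = inject_artifacts(rec, sp)
    assert len(out.metadata["artifact_events"]) == len(rec.events)
    es = epoch_by_events(out, ("congruent", "incongruent"), -0.1, 0.7)
    es, frac = reject_epochs(es, 75.0)
    assert frac == 1.0


def test_artifact_fraction_binomial(montage64):
    m = montage64.subset(["Cz", "CPz", "Pz", "Fz"])
    sp = make_subject(artifact_rate=0.12, noise_scale=1.0)
    rec = simulate_n400(sp, 500, m, isi_s=1.0)
    out = inject_artifacts(rec, sp)
    frac = len(out.metadata["artifact_events"]) / len(rec.events)
    assert frac == pytest.approx(0.12, abs=0.03)
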