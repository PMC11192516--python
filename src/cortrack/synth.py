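"""Synthetic EEG cohorts with known ground truth.

The generator produces two recordings per simulated subject:

* an *entrainment* recording — trials of isochronous four-word sentences in
  which the neural response is modeled as phase-locked sinusoids at exactly
  the sentential, phrasal and syllabic rates, projected through a smooth
  topographic gain map and embedded in 1/f ("pink") background noise;
* an *N400* recording — one critical-word marker per sentence
  (congruent/incongruent), each adding a Gaussian-windowed negative
  deflection (SD 80 ms) on centro-parietal channels, with the
  incongruent-minus-congruent ROI window mean calibrated to a per-subject
  effect size; plus pink noise and optional large boxcar artifacts.

Cohort-level coupling: a Gaussian copula imposes a target Spearman
correlation between a subject's sentential tracking amplitude and the
magnitude of their N400 effect (and, optionally, their behavioral
comprehension scores), so the correlation analysis downstream has a known
ground truth.  All draws are pure functions of the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import ndtr

from . import paradigm as par
from .errors import DegenerateDistribution
from .io import Recording
from .montage import Montage

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "draw_cohort",
    "simulate_entrainment",
    "simulate_n400",
    "inject_artifacts",
    "pink_noise",
    "evoked_noise",
    "population_n400_mean",
    "n400_template",
    "n400_scales",
]

#: per-field truncation bounds for cohort marginals
_BOUNDS = {
    "amp_sentential": (0.0, np.inf),
    "amp_phrasal": (0.0, np.inf),
    "amp_syllabic": (0.0, np.inf),
    "n400_magnitude": (0.0, np.inf),
    "noise_scale": (1e-3, np.inf),
    "comprehension_rating": (0.0, 4.0),
    "question_accuracy": (0.0, 1.0),
    "listening_score": (0.0, 1.0),
}

#: N400 template width (Gaussian SD, ms) and effect-calibration window (ms)
N400_TEMPLATE_SD_MS = 80.0
N400_EFFECT_WINDOW_MS = (300.0, 700.0)


@dataclass
class SubjectParams:
    """Latent quantities of one simulated subject.

    ``n400_effect`` is the incongruent-minus-congruent ROI-mean amplitude
    over the 300-700 ms window in the noise-free limit (negative for the
    canonical N400).  Amplitudes and noise are in microvolts.
    """

    subject_id: str
    group: str
    amp_sentential: float
    amp_phrasal: float
    amp_syllabic: float
    phase_sentential: float
    phase_phrasal: float
    phase_syllabic: float
    n400_effect: float
    n400_latency_ms: float
    noise_scale: float
    artifact_rate: float
    seed: int
    comprehension_rating: float = 0.0
    question_accuracy: float = 1.0
    listening_score: float = 1.0

    def __post_init__(self) -> None:
        for name in ("amp_sentential", "amp_phrasal", "amp_syllabic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        if not 0 < self.n400_latency_ms < 700:
            raise ValueError("n400_latency_ms must lie in (0, 700)")


def _default_distributions() -> dict[str, tuple[float, float]]:
    # native-listener-like cohort: tracks all three rates, canonical N400
    return {
        "amp_sentential": (0.8, 0.3),
        "amp_phrasal": (1.0, 0.35),
        "amp_syllabic": (1.5, 0.5),
        "n400_magnitude": (1.2, 0.8),
        "noise_scale": (10.0, 2.0),
        "comprehension_rating": (3.68, 0.5),
        "question_accuracy": (0.95, 0.04),
        "listening_score": (0.97, 0.02),
    }


@dataclass
class CohortSpec:
    """Recipe for drawing a cohort of :class:`SubjectParams`.

    ``coupling_rho`` is the target Spearman correlation, across subjects,
    between ``amp_sentential`` and ``|n400_effect|``; it is realized by a
    Gaussian copula, so it holds for the population regardless of the
    marginal distributions.  ``behavior_coupling_rho`` couples the same
    latent factor to the comprehension rating and listening score.
    """

    group: str = "NL"
    n_subjects: int = 22
    coupling_rho: float = 0.6
    behavior_coupling_rho: float = 0.0
    n400_latency_ms: float = 400.0
    artifact_rate: float = 0.123
    master_seed: int = 0
    distributions: dict[str, tuple[float, float]] = field(
        default_factory=_default_distributions
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for rho in (self.coupling_rho, self.behavior_coupling_rho):
            if abs(rho) > 1:
                raise ValueError("coupling rho must lie in [-1, 1]")


def _copula_r(rho_s: float) -> float:
    """Latent Pearson correlation realizing Spearman ``rho_s`` (Gaussian copula)."""
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    if abs(r) >= 1.0 - 1e-12:  # avoid float dust breaking comonotonicity
        r = math.copysign(1.0, r)
    return r


def _marginal(u: np.ndarray, key: str, mean: float, sd: float) -> np.ndarray:
    """Truncated-normal quantile transform of uniforms ``u``."""
    lo, hi = _BOUNDS[key]
    if sd == 0:
        return np.full_like(u, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def population_n400_mean(cs: CohortSpec) -> float:
    """Population mean of the (signed) N400 effect under ``cs``."""
    mean, sd = cs.distributions["n400_magnitude"]
    if sd == 0:
        return -mean
    lo, hi = _BOUNDS["n400_magnitude"]
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return -float(sps.truncnorm.mean(a, b, loc=mean, scale=sd))


def draw_cohort(cs: CohortSpec) -> list[SubjectParams]:
    """Draw ``cs.n_subjects`` parameter sets, deterministic given the seed."""
    for key, (_, sd) in cs.distributions.items():
        if sd < 0:
            raise DegenerateDistribution(f"{key} has SD {sd} < 0")
    n = cs.n_subjects
    ss = np.random.SeedSequence(cs.master_seed)
    children = ss.spawn(n + 1)
    rng = np.random.default_rng(children[0])

    z = rng.standard_normal((n, 8))
    u_sent = z[:, 0]
    r1 = _copula_r(cs.coupling_rho)
    z_n400 = r1 * u_sent + math.sqrt(max(0.0, 1 - r1**2)) * z[:, 1]
    rb = _copula_r(cs.behavior_coupling_rho)
    sb = math.sqrt(max(0.0, 1 - rb**2))
    z_rating = rb * u_sent + sb * z[:, 2]
    z_listen = rb * u_sent + sb * z[:, 3]

    latents = {
        "amp_sentential": u_sent,
        "n400_magnitude": z_n400,
        "comprehension_rating": z_rating,
        "listening_score": z_listen,
        "amp_phrasal": z[:, 4],
        "amp_syllabic": z[:, 5],
        "noise_scale": z[:, 6],
        "question_accuracy": z[:, 7],
    }
    values = {
        key: _marginal(ndtr(lat), key, *cs.distributions[key])
        for key, lat in latents.items()
    }
    phases = rng.uniform(0.0, 2 * np.pi, size=(n, 3))

    subjects = []
    for i in range(n):
        seed = int(children[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        subjects.append(
            SubjectParams(
                subject_id=f"{cs.group}{i + 1:02d}",
                group=cs.group,
                amp_sentential=float(values["amp_sentential"][i]),
                amp_phrasal=float(values["amp_phrasal"][i]),
                amp_syllabic=float(values["amp_syllabic"][i]),
                phase_sentential=float(phases[i, 0]),
                phase_phrasal=float(phases[i, 1]),
                phase_syllabic=float(phases[i, 2]),
                n400_effect=-float(values["n400_magnitude"][i]),
                n400_latency_ms=cs.n400_latency_ms,
                noise_scale=float(values["noise_scale"][i]),
                artifact_rate=cs.artifact_rate,
                seed=seed,
                comprehension_rating=float(values["comprehension_rating"][i]),
                question_accuracy=float(values["question_accuracy"][i]),
                listening_score=float(values["listening_score"][i]),
            )
        )
    return subjects


# ---------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------


def pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs_hz: float,
    rms: float,
    exponent: float = 1.0,
    dtype: np.dtype = np.float64,
) -> np.ndarray:
    """Gaussian 1/f^exponent noise with expected per-sample RMS ``rms``.

    Synthesized in the frequency domain (independent complex-Gaussian bins
    with amplitude proportional to f^(-exponent/2), DC zero), normalized so
    the ensemble-average variance equals ``rms**2``.  The last axis of
    ``shape`` is time.  Internally the series is synthesized at the next
    FFT-friendly length and cropped, which leaves the process stationary.
    """
    from scipy.fft import irfft, next_fast_len

    *lead, n_out = shape
    n = next_fast_len(n_out, real=True)
    nf = n // 2 + 1
    f = np.fft.rfftfreq(n, 1.0 / fs_hz)
    amp = np.zeros(nf)
    amp[1:] = f[1:] ** (-exponent / 2.0)

    dtype = np.dtype(dtype)
    cplx = np.complex64 if dtype == np.float32 else np.complex128
    ampd = amp.astype(dtype)
    xr = rng.standard_normal((*lead, nf), dtype=dtype)
    xi = rng.standard_normal((*lead, nf), dtype=dtype)
    X = np.empty((*lead, nf), dtype=cplx)
    X.real = xr * ampd
    X.imag = xi * ampd
    X[..., 0] = 0.0
    even = n % 2 == 0
    if even:
        X[..., -1] = ampd[-1] * dtype.type(math.sqrt(2.0)) * xr[..., -1]
    # ensemble E[sum x^2] = (1/n) * sum_k E|X_k|^2 over the full (two-sided)
    # spectrum; every retained bin contributes E|X_k|^2 = 2 amp_k^2
    mid = amp[1:-1] if even else amp[1:]
    e_sum = 2.0 * (2.0 * np.sum(mid**2) + (2.0 * amp[-1] ** 2 if even else 0.0))
    var = e_sum / n**2
    if var > 0:
        X *= rms / math.sqrt(var)
    return irfft(X, n=n)[..., :n_out]


def evoked_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs_hz: float,
    noise_scale: float,
    n_trials: int,
) -> np.ndarray:
    """Noise part of a trial-averaged signal, drawn directly.

    The mean of ``n_trials`` independent Gaussian pink-noise realizations
    is itself pink noise with RMS scaled by 1/sqrt(n_trials); this draws
    that average in one step (exact in distribution), which keeps
    large Monte-Carlo calibration experiments affordable.
    """
    return pink_noise(rng, shape, fs_hz, noise_scale / math.sqrt(n_trials))


# ---------------------------------------------------------------------
# entrainment recording
# ---------------------------------------------------------------------


def simulate_entrainment(
    sp: SubjectParams,
    spec: par.ParadigmSpec,
    m: Montage,
    gap_s: float = 1.0,
    dtype: np.dtype = np.float32,
) -> Recording:
    """Continuous entrainment session: ``spec.n_trials`` trials of sentences.

    Within each trial, channel ``c`` carries
    ``sum_k amp_k * gain_osc(c) * sin(2 pi f_k t + phase_k)`` for the three
    tagged rates (``t`` relative to trial onset), on top of pink noise.
    Events mark every trial onset (``trial``) and sentence onset
    (``sentence``).
    """
    fs = spec.fs_hz
    sent_dur = par.sentence_duration(spec)
    trial_samples = int(round(spec.sentences_per_trial * sent_dur * fs))
    gap_samples = int(round(gap_s * fs))
    total = gap_samples + spec.n_trials * (trial_samples + gap_samples)

    rng = np.random.default_rng([sp.seed, 0])
    data = pink_noise(rng, (m.n_channels, total), fs, sp.noise_scale,
                      dtype=dtype)

    tf = par.tag_frequencies(spec)
    t = np.arange(trial_samples) / fs
    sig = (
        sp.amp_sentential * np.sin(2 * np.pi * tf.sentential_hz * t + sp.phase_sentential)
        + sp.amp_phrasal * np.sin(2 * np.pi * tf.phrasal_hz * t + sp.phase_phrasal)
        + sp.amp_syllabic * np.sin(2 * np.pi * tf.syllabic_hz * t + sp.phase_syllabic)
    )
    proj = (m.gain_osc[:, None] * sig[None, :]).astype(data.dtype)

    events: list[tuple[int, str]] = []
    sent_samples = int(round(sent_dur * fs))
    for k in range(spec.n_trials):
        onset = gap_samples + k * (trial_samples + gap_samples)
        data[:, onset : onset + trial_samples] += proj
        events.append((onset, "trial"))
        for j in range(spec.sentences_per_trial):
            events.append((onset + j * sent_samples, "sentence"))

    return Recording(
        fs_hz=fs,
        channel_labels=list(m.labels),
        data=data,
        events=events,
        metadata={
            "kind": "entrainment",
            "subject_id": sp.subject_id,
            "group": sp.group,
            "seed": sp.seed,
        },
    )


# ---------------------------------------------------------------------
# N400 recording
# ---------------------------------------------------------------------


def n400_template(offsets: np.ndarray, fs_hz: float, latency_ms: float) -> np.ndarray:
    """Gaussian deflection sampled at integer offsets from the marker."""
    t_ms = offsets / fs_hz * 1000.0
    return np.exp(-((t_ms - latency_ms) ** 2) / (2 * N400_TEMPLATE_SD_MS**2))


def n400_scales(
    sp: SubjectParams, m: Montage, fs_hz: float, base_uv: float = -1.5
) -> tuple[float, float]:
    """Template scale factors (shared base, incongruent increment).

    Calibrated so that the ROI-mean amplitude over the 300-700 ms effect
    window equals ``base_uv`` for congruent markers and
    ``base_uv + sp.n400_effect`` for incongruent ones in the noise-free
    limit (discrete window/template overlap correction).
    """
    w0, w1 = N400_EFFECT_WINDOW_MS
    win_off = np.arange(int(round(w0 / 1000 * fs_hz)), int(round(w1 / 1000 * fs_hz)))
    win_mean = float(np.mean(n400_template(win_off, fs_hz, sp.n400_latency_ms)))
    roi_idx = [m.index(lb) for lb in m.roi]
    roi_gain = float(np.mean(m.gain_erp[roi_idx]))
    if win_mean <= 0 or roi_gain <= 0:
        raise ValueError("degenerate template/ROI gain calibration")
    return base_uv / (win_mean * roi_gain), sp.n400_effect / (win_mean * roi_gain)


def simulate_n400(
    sp: SubjectParams,
    n_sentences_per_condition: int,
    m: Montage,
    isi_s: float = 2.5,
    schedule_seed: int | None = None,
    base_uv: float = -1.5,
    fs_hz: float = 500.0,
    dtype: np.dtype = np.float32,
) -> Recording:
    """Continuous N400 session with one critical-word marker per sentence.

    Both conditions evoke a shared deflection whose ROI-mean over the
    300-700 ms window equals ``base_uv``; the incongruent condition adds a
    calibrated increment such that the incongruent-minus-congruent ROI-mean
    window amplitude equals ``sp.n400_effect`` in the noise-free limit.
    The condition schedule depends only on ``schedule_seed`` (derived from
    ``sp.seed`` when not given), so noise seeds can vary under a fixed
    schedule.
    """
    if n_sentences_per_condition < 1:
        raise ValueError("n_sentences_per_condition must be >= 1")
    fs = fs_hz
    n_tot = 2 * n_sentences_per_condition
    labels = ["congruent"] * n_sentences_per_condition + [
        "incongruent"
    ] * n_sentences_per_condition
    sched_rng = np.random.default_rng(
        [sp.seed, 3] if schedule_seed is None else [int(schedule_seed), 3]
    )
    order = sched_rng.permutation(n_tot)
    labels = [labels[i] for i in order]

    lead_s = 2.0
    total = int(round((lead_s + n_tot * isi_s + 1.0) * fs))
    rng = np.random.default_rng([sp.seed, 2])
    data = pink_noise(rng, (m.n_channels, total), fs, sp.noise_scale,
                      dtype=dtype)

    base_scale, diff_scale = n400_scales(sp, m, fs, base_uv)

    span = np.arange(0, int(round(0.7 * fs)) + int(round(4 * N400_TEMPLATE_SD_MS / 1000 * fs)))
    tpl = n400_template(span, fs, sp.n400_latency_ms)
    gains = m.gain_erp[:, None]

    events: list[tuple[int, str]] = []
    for i, lab in enumerate(labels):
        s0 = int(round((lead_s + i * isi_s) * fs))
        scale = base_scale + (diff_scale if lab == "incongruent" else 0.0)
        sl = slice(s0, s0 + span.size)
        data[:, sl] += gains * (scale * tpl)[None, :]
        events.append((s0, lab))

    return Recording(
        fs_hz=fs,
        channel_labels=list(m.labels),
        data=data,
        events=events,
        metadata={
            "kind": "n400",
            "subject_id": sp.subject_id,
            "group": sp.group,
            "seed": sp.seed,
            "true_n400_effect_uv": sp.n400_effect,
            "n400_latency_ms": sp.n400_latency_ms,
        },
    )


# ---------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------


def inject_artifacts(
    rec: Recording,
    sp: SubjectParams,
    window_s: tuple[float, float] = (-0.1, 0.7),
) -> Recording:
    """Add large boxcar excursions to a random subset of event segments.

    Each event-aligned segment is contaminated independently with
    probability ``sp.artifact_rate``; the excursion amplitude is drawn
    uniformly from +/-[100, 300] uV on a random channel subset and spans at
    least half of the epoch window.  Ground-truth flagged event indices are
    stored in ``metadata['artifact_events']``.
    """
    out = rec.copy()
    rng = np.random.default_rng([sp.seed, 1])
    fs = rec.fs_hz
    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    n_ch = len(rec.channel_labels)
    flagged: list[int] = []
    for ei, (s0, _) in enumerate(rec.events):
        if rng.random() >= sp.artifact_rate:
            continue
        amp = rng.uniform(100.0, 300.0) * rng.choice([-1.0, 1.0])
        k = int(rng.integers(1, max(2, n_ch // 8) + 1))
        chans = rng.choice(n_ch, size=k, replace=False)
        width = i1 - i0
        length = int(rng.integers(width // 2, width + 1))
        start = s0 + i0 + int(rng.integers(0, width - length + 1))
        lo = max(0, start)
        hi = min(rec.n_samples, start + length)
        out.data[np.ix_(chans, np.arange(lo, hi))] += amp
        flagged.append(ei)
    out.metadata["artifact_events"] = flagged
    return out
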