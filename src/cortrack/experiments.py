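"""Monte-Carlo validation experiments for the analysis pipeline.

These experiments check the statistical behaviour of the pipeline against
the generator's ground truth: type-I error of the peak test on null
cohorts, detection of tagged rates at the frozen cohort settings, recovery
and CI coverage of the injected N400 effect, false-discovery control of
the point-wise map, and recovery of the copula-imposed correlation.

Where thousands of simulated subjects are needed, the trial-averaging step
is drawn directly via :func:`cortrack.synth.evoked_noise` (exact in
distribution for Gaussian noise) and spatially scaled-down montages are
used; the analysis side always runs the same package code as the full
pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import paradigm as par
from .erp import pointwise_fdr_map, roi_window_effect
from .montage import REDUCED_16, Montage, standard_64
from .stats import correlate_measures
from .synth import (
    CohortSpec,
    SubjectParams,
    _marginal,
    draw_cohort,
    evoked_noise,
    n400_scales,
    n400_template,
    population_n400_mean,
)
from .tagging import evoked_power, group_peak_test, subject_peak_pair

__all__ = [
    "type_i_error",
    "detection_counts",
    "ci_coverage",
    "fdr_null_mean_fdp",
    "correlation_recovery",
    "fast_cohort_erps",
]


def _child_seeds(seed: int, tag: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence([int(seed), int(tag)]).spawn(n)


def type_i_error(
    n_cohorts: int = 1000,
    seed: int = 0,
    n_subjects: int = 22,
    n_channels: int = 16,
    n_trials: int = 30,
    noise_dist: tuple[float, float] = (10.0, 2.0),
    alpha: float = 0.05,
    spec: par.ParadigmSpec | None = None,
) -> dict[str, float]:
    """Rejection rates of the one-tailed peak test on amp = 0 cohorts.

    Each cohort is pure 1/f noise passed through evoked power,
    electrode-average and the per-rate peak test; returns per-rate
    rejection rates and the rate pooled over the three tagged bins.
    """
    spec = spec or par.ParadigmSpec()
    n_samp = int(round(par.epoch_duration(spec) * spec.fs_hz))
    bins = par.tag_bins(spec)
    rejections = {r: 0 for r in bins}
    for child in _child_seeds(seed, 101, n_cohorts):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(n_subjects)
        noise = _marginal(ndtr(z), "noise_scale", *noise_dist)
        x = evoked_noise(
            rng, (n_subjects, n_channels, n_samp), spec.fs_hz, 1.0, n_trials
        )
        x *= noise[:, None, None]
        pairs = {r: [] for r in bins}
        for s in range(n_subjects):
            ss = evoked_power(x[s], spec.fs_hz)
            for r, b in bins.items():
                pairs[r].append(subject_peak_pair(ss, b))
        for r in bins:
            res = group_peak_test(np.array(pairs[r]), alpha=alpha, label=r)
            rejections[r] += int(res.significant)
    out = {r: c / n_cohorts for r, c in rejections.items()}
    out["pooled"] = sum(rejections.values()) / (3 * n_cohorts)
    return out


def detection_counts(
    cfg: dict,
    group: str,
    seeds: list[int],
    montage: Montage | None = None,
    alpha: float = 0.05,
) -> dict[str, int]:
    """Count cohorts (one per seed) with a significant peak, per rate.

    Runs the full simulate -> filter -> re-reference -> epoch -> evoked
    power -> peak-test path at the frozen cohort settings of ``cfg`` on a
    compact montage.
    """
    from .pipeline import cohort_spec_from_config, entrainment_group_results

    spec = par.ParadigmSpec.from_dict(cfg["paradigm"])
    m = montage or standard_64().subset(REDUCED_16)
    ecfg = cfg["entrainment"]
    counts = {r: 0 for r in par.RATE_MULTIPLIERS}
    for seed in seeds:
        cs = cohort_spec_from_config(cfg, group, int(seed))
        subjects = draw_cohort(cs)
        results, _ = entrainment_group_results(
            subjects, spec, m,
            band_hz=tuple(ecfg["band_hz"]),
            k=int(ecfg["neighbor_k"]),
            alpha=alpha,
        )
        for r, res in results.items():
            counts[r] += int(res.significant)
    return counts


# ---------------------------------------------------------------------
# fast ERP-level cohorts
# ---------------------------------------------------------------------


def fast_cohort_erps(
    subjects: list[SubjectParams],
    m: Montage,
    rng: np.random.Generator,
    fs_hz: float = 500.0,
    n_epochs_per_cond: int = 53,
    epoch_s: tuple[float, float] = (-0.1, 0.7),
    noise: bool = True,
) -> tuple[list[dict[str, np.ndarray]], list[str]]:
    """Per-subject condition ERPs drawn at the trial-average level.

    The noise-free part reproduces exactly what epoching + averaging of a
    ``simulate_n400`` recording yields; the noise part uses the
    1/sqrt(n) averaging identity.  Baseline correction over the
    pre-stimulus interval is applied, mirroring the pipeline.
    """
    i0 = int(round(epoch_s[0] * fs_hz))
    i1 = int(round(epoch_s[1] * fs_hz))
    offs = np.arange(i0, i1)
    n_base = int(round(-epoch_s[0] * fs_hz))
    gains = m.gain_erp[:, None]
    erps = []
    for sp in subjects:
        tpl = n400_template(offs, fs_hz, sp.n400_latency_ms)
        base_scale, diff_scale = n400_scales(sp, m, fs_hz)
        cong = gains * (base_scale * tpl)[None, :]
        inc = gains * ((base_scale + diff_scale) * tpl)[None, :]
        if noise:
            nz = evoked_noise(
                rng, (2, m.n_channels, offs.size), fs_hz,
                sp.noise_scale, n_epochs_per_cond,
            )
            cong = cong + nz[0]
            inc = inc + nz[1]
        pair = {}
        for label, e in (("congruent", cong), ("incongruent", inc)):
            pair[label] = e - e[:, :n_base].mean(axis=1, keepdims=True)
        erps.append(pair)
    return erps, list(m.labels)


def ci_coverage(
    n_runs: int = 500,
    seed: int = 0,
    n_subjects: int = 22,
    spec_kwargs: dict | None = None,
    window_ms: tuple[float, float] = (300.0, 700.0),
) -> float:
    """Fraction of cohorts whose 95% CI covers the true population effect."""
    full = standard_64()
    m = full.subset(full.roi)  # ROI channels only
    covered = 0
    cs0 = CohortSpec(**(spec_kwargs or {}))
    truth = population_n400_mean(cs0)
    for child in _child_seeds(seed, 202, n_runs):
        rng = np.random.default_rng(child)
        cs = CohortSpec(
            **{**(spec_kwargs or {}), "n_subjects": n_subjects,
               "master_seed": int(child.generate_state(1)[0] & 0x7FFFFFFF)}
        )
        subjects = draw_cohort(cs)
        erps, labels = fast_cohort_erps(subjects, m, rng)
        eff = roi_window_effect(erps, m.roi, window_ms, labels, 500.0, -0.1)
        if eff.ci95[0] <= truth <= eff.ci95[1]:
            covered += 1
    return covered / n_runs


def fdr_null_mean_fdp(
    n_runs: int = 200,
    seed: int = 0,
    n_subjects: int = 22,
    n_channels: int = 16,
    n_epochs_per_cond: int = 53,
    noise_dist: tuple[float, float] = (10.0, 2.0),
    q: float = 0.05,
    n_samples: int = 400,
) -> float:
    """Mean false-discovery proportion of the point-wise map on null data.

    Both conditions are pure noise, so any FDR-significant point is a
    false discovery and the per-run FDP is 1 whenever the mask is
    non-empty.
    """
    fdp = 0.0
    for child in _child_seeds(seed, 303, n_runs):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(n_subjects)
        noise = _marginal(ndtr(z), "noise_scale", *noise_dist)
        nz = evoked_noise(
            rng, (n_subjects, 2, n_channels, n_samples), 500.0, 1.0,
            n_epochs_per_cond,
        )
        nz *= noise[:, None, None, None]
        nz -= nz[:, :, :, :50].mean(axis=3, keepdims=True)
        erps = [
            {"congruent": nz[s, 0], "incongruent": nz[s, 1]}
            for s in range(n_subjects)
        ]
        pw = pointwise_fdr_map(
            erps, 500.0, -0.1, [f"ch{i}" for i in range(n_channels)], q=q
        )
        fdp += 1.0 if pw.mask.any() else 0.0
    return fdp / n_runs


def correlation_recovery(
    n_runs: int = 500,
    coupling_rho: float = 0.6,
    seed: int = 0,
    n_subjects: int = 22,
) -> dict[str, float]:
    """Recovery of the copula-imposed tracking/N400-magnitude correlation."""
    rhos = []
    for child in _child_seeds(seed, 404, n_runs):
        cs = CohortSpec(
            coupling_rho=coupling_rho,
            n_subjects=n_subjects,
            master_seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
        )
        subjects = draw_cohort(cs)
        table = pd.DataFrame(
            {
                "amp_sentential": [sp.amp_sentential for sp in subjects],
                "n400_magnitude": [abs(sp.n400_effect) for sp in subjects],
            }
        )
        res = correlate_measures(table, [("amp_sentential", "n400_magnitude")])[0]
        rhos.append(res.rho)
    rhos_arr = np.array(rhos)
    return {
        "fraction_positive": float(np.mean(rhos_arr > 0)),
        "median_rho": float(np.median(rhos_arr)),
        "mean_rho": float(np.mean(rhos_arr)),
    }
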