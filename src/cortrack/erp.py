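"""N400 analysis: condition ERPs, ROI window contrasts, point-wise FDR maps.

Inference is at the subject level throughout: trial averages per condition
per subject, then paired tests across subjects.  Window means use
half-open sample windows ``[start, end)`` consistent with the epoching
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import MissingChannel, MissingCondition
from .preprocess import EpochSet
from .stats import bh_fdr, paired_t

__all__ = [
    "ErpEffect",
    "PointwiseMap",
    "condition_erps",
    "roi_window_effect",
    "pointwise_fdr_map",
]

CONDITIONS = ("congruent", "incongruent")


@dataclass
class ErpEffect:
    """Paired congruency contrast of ROI window means across subjects."""

    window_ms: tuple[float, float]
    congruent_uv: np.ndarray  # per-subject ROI-window mean, congruent
    incongruent_uv: np.ndarray
    effect_uv: float  # mean of incongruent - congruent
    t_statistic: float
    df: int
    p_two_tailed: float
    ci95: tuple[float, float]

    @property
    def per_subject_effect_uv(self) -> np.ndarray:
        return self.incongruent_uv - self.congruent_uv


@dataclass
class PointwiseMap:
    """Paired t and p at every (electrode, sample), with a BH-FDR mask."""

    t: np.ndarray  # (n_channels, n_samples)
    p: np.ndarray
    mask: np.ndarray  # bool, FDR-significant at q
    q: float
    times_s: np.ndarray
    channel_labels: list[str]


def condition_erps(
    es: EpochSet, conditions: tuple[str, ...] = CONDITIONS
) -> dict[str, np.ndarray]:
    """Trial means per condition over retained epochs -> label: (ch, samp)."""
    cond = np.asarray(es.conditions)
    out = {}
    for label in conditions:
        sel = es.retained & (cond == label)
        if not sel.any():
            raise MissingCondition(label)
        out[label] = es.data[sel].mean(axis=0)
    return out


def _window_slice(
    win_ms: tuple[float, float], fs_hz: float, t0_offset_s: float, n_samples: int
) -> slice:
    i0 = int(round((win_ms[0] / 1000.0 - t0_offset_s) * fs_hz))
    i1 = int(round((win_ms[1] / 1000.0 - t0_offset_s) * fs_hz))
    if not (0 <= i0 < i1 <= n_samples):
        raise ValueError(f"window {win_ms} ms outside the epoch")
    return slice(i0, i1)


def roi_window_effect(
    erps: list[dict[str, np.ndarray]],
    roi_labels: list[str],
    win_ms: tuple[float, float],
    channel_labels: list[str],
    fs_hz: float,
    t0_offset_s: float,
) -> ErpEffect:
    """Paired congruency contrast of the ROI-mean amplitude in a window.

    ``erps`` holds one condition->ERP dict per subject.  Per subject and
    condition, the amplitude is averaged over the ROI channels and the
    window samples; a two-tailed paired t across subjects tests the
    incongruent-minus-congruent difference, with a 95% CI on its mean.
    """
    idx = []
    for lb in roi_labels:
        if lb not in channel_labels:
            raise MissingChannel(lb)
        idx.append(channel_labels.index(lb))
    n_samples = next(iter(erps[0].values())).shape[1]
    sl = _window_slice(win_ms, fs_hz, t0_offset_s, n_samples)
    cong = np.array([e["congruent"][idx, sl].mean() for e in erps])
    inc = np.array([e["incongruent"][idx, sl].mean() for e in erps])
    t, df, p = paired_t(inc, cong, alternative="two-sided")
    d = inc - cong
    n = d.size
    sem = d.std(ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, df)
    mean = float(d.mean())
    return ErpEffect(
        window_ms=tuple(win_ms),
        congruent_uv=cong,
        incongruent_uv=inc,
        effect_uv=mean,
        t_statistic=t,
        df=df,
        p_two_tailed=p,
        ci95=(mean - tcrit * sem, mean + tcrit * sem),
    )


def pointwise_fdr_map(
    erps: list[dict[str, np.ndarray]],
    fs_hz: float,
    t0_offset_s: float,
    channel_labels: list[str],
    q: float = 0.05,
) -> PointwiseMap:
    """Paired t at every (electrode, sample), BH-corrected over the full map.

    The FDR family is the joint electrode x time collection, the more
    conservative reading of a point-wise map correction.
    """
    if len(erps) < 2:
        raise ValueError("need >= 2 subjects")
    diff = np.stack([e["incongruent"] - e["congruent"] for e in erps])
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    mask = bh_fdr(p.ravel(), q).reshape(p.shape)
    times = t0_offset_s + np.arange(diff.shape[2]) / fs_hz
    return PointwiseMap(
        t=t, p=p, mask=mask, q=q, times_s=times,
        channel_labels=list(channel_labels),
    )
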