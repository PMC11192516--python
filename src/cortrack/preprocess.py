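"""Filtering, re-referencing, interpolation, epoching and rejection.

Conventions shared by both experiments: event sample indices are 0-based;
epoch windows are half-open ``[round(e + tmin*fs), round(e + tmax*fs))`` in
samples; the +/- amplitude rejection criterion is evaluated after
referencing, filtering and baseline correction, over every channel kept in
the epoch set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
from scipy import signal
from scipy.spatial import Delaunay

from .errors import (
    BadBand,
    EmptyWindow,
    IslandChannel,
    MissingChannel,
    NoEvents,
)
from .io import Recording
from .montage import Montage

log = logging.getLogger("cortrack.preprocess")

__all__ = [
    "EpochSet",
    "fir_bandpass",
    "design_bandpass",
    "rereference",
    "drop_channels",
    "interpolate_channels",
    "epoch_by_events",
    "reject_epochs",
    "baseline_correct",
]


@dataclass
class EpochSet:
    """Epochs x channels x samples with per-epoch labels and retention flags."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs_hz: float
    t0_offset_s: float  # time of sample 0 relative to the lock event
    conditions: list[str]
    retained: np.ndarray  # (n_epochs,) bool
    channel_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n_ep, n_ch, _ = self.data.shape
        if len(self.conditions) != n_ep or self.retained.shape != (n_ep,):
            raise ValueError("conditions/retained must match epoch count")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels must match channel count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the lock event."""
        return self.t0_offset_s + np.arange(self.n_samples) / self.fs_hz


# ---------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------


def design_bandpass(lo_hz: float, hi_hz: float, fs_hz: float) -> np.ndarray:
    """Hamming-windowed-sinc band-pass kernel.

    The transition width is ``min(lo_hz, 0.1*hi_hz)`` and the order follows
    the classic Hamming rule ``ceil(3.3 / (width / fs))`` (odd tap count,
    linear phase).
    """
    if not 0 < lo_hz < hi_hz < fs_hz / 2:
        raise BadBand(f"need 0 < {lo_hz} < {hi_hz} < {fs_hz / 2}")
    width = min(lo_hz, 0.1 * hi_hz)
    order = math.ceil(3.3 / (width / fs_hz))
    ntaps = order + 1
    if ntaps % 2 == 0:
        ntaps += 1
    return signal.firwin(
        ntaps, [lo_hz, hi_hz], pass_zero=False, window="hamming", fs=fs_hz
    )


def fir_bandpass(rec: Recording, lo_hz: float, hi_hz: float) -> Recording:
    """Zero-phase (forward-backward) FIR band-pass of a recording.

    Forward-backward application of the symmetric kernel is computed in a
    single pass by convolving with the kernel's autocorrelation, with odd
    reflection padding at the edges (same endpoint handling as ``filtfilt``).
    """
    h = design_bandpass(lo_hz, hi_hz, rec.fs_hz)
    h2 = np.convolve(h, h)  # |H|^2, still linear phase
    x = rec.data
    h2 = h2.astype(x.dtype, copy=False)  # keep single precision cheap
    n = x.shape[1]
    pad = min(h2.size // 2, n - 1)
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right], axis=1)
    y = signal.fftconvolve(xp, h2[None, :], mode="same")[:, pad : pad + n]
    out = rec.copy()
    out.data = y
    return out


# ---------------------------------------------------------------------
# referencing / channel repair
# ---------------------------------------------------------------------


def drop_channels(rec: Recording, labels: Iterable[str], *, strict: bool = False) -> Recording:
    """Remove the named channels (silently skipping absent ones unless strict)."""
    labels = set(labels)
    absent = labels - set(rec.channel_labels)
    if absent and strict:
        raise MissingChannel(str(sorted(absent)))
    keep = [i for i, lb in enumerate(rec.channel_labels) if lb not in labels]
    out = rec.copy()
    out.channel_labels = [rec.channel_labels[i] for i in keep]
    out.data = rec.data[keep]
    return out


def rereference(
    rec: Recording,
    scheme: str,
    mastoid_labels: tuple[str, str] = ("M1", "M2"),
) -> Recording:
    """Re-express every channel relative to a reference.

    ``scheme='common_average'`` subtracts the instantaneous mean over all
    channels present; ``scheme='linked_mastoids'`` subtracts the mean of the
    two named mastoid channels.
    """
    out = rec.copy()
    if scheme == "common_average":
        out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    elif scheme == "linked_mastoids":
        idx = []
        for lb in mastoid_labels:
            if lb not in rec.channel_labels:
                raise MissingChannel(lb)
            idx.append(rec.channel_labels.index(lb))
        ref = rec.data[idx].mean(axis=0, keepdims=True)
        out.data = rec.data - ref
    else:
        raise ValueError(f"unknown reference scheme: {scheme}")
    return out


def interpolate_channels(
    rec: Recording, bad_labels: Iterable[str], layout: Montage
) -> Recording:
    """Replace bad channels by inverse-distance means of Delaunay neighbors.

    Neighbors are adjacent vertices of the Delaunay triangulation of the
    2-D layout; only good neighbors contribute (weights 1/distance).
    """
    bad = list(bad_labels)
    if not bad:
        return rec.copy()
    for lb in bad + list(rec.channel_labels):
        layout.index(lb)  # MissingChannel if layout lacks it
    pos = np.array([layout.pos[layout.index(lb)] for lb in rec.channel_labels])
    tri = Delaunay(pos)
    neighbors: dict[int, set[int]] = {i: set() for i in range(len(pos))}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    neighbors[a].add(b)
    bad_idx = {rec.channel_labels.index(lb) for lb in bad if lb in rec.channel_labels}
    out = rec.copy()
    for i in sorted(bad_idx):
        good = [j for j in neighbors[i] if j not in bad_idx]
        if not good:
            raise IslandChannel(rec.channel_labels[i])
        d = np.linalg.norm(pos[good] - pos[i], axis=1)
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum()
        out.data[i] = w @ rec.data[good]
    return out


# ---------------------------------------------------------------------
# epoching / rejection / baseline
# ---------------------------------------------------------------------


def epoch_by_events(
    rec: Recording,
    label_filter: str | Iterable[str] | Callable[[str], bool],
    tmin_s: float,
    tmax_s: float,
) -> EpochSet:
    """Cut half-open epochs ``[round(e+tmin*fs), round(e+tmax*fs))``.

    ``label_filter`` selects events by exact label (string or collection)
    or by predicate.  Epochs overrunning the recording are dropped with a
    logged warning.
    """
    if tmin_s >= tmax_s:
        raise ValueError("tmin_s must be < tmax_s")
    if callable(label_filter):
        pred = label_filter
    elif isinstance(label_filter, str):
        pred = lambda lb: lb == label_filter  # noqa: E731
    else:
        allowed = set(label_filter)
        pred = lambda lb: lb in allowed  # noqa: E731
    sel = [(s, lb) for s, lb in rec.events if pred(lb)]
    if not sel:
        raise NoEvents("no events match the filter")
    fs = rec.fs_hz
    epochs, conds, dropped = [], [], 0
    for s, lb in sel:
        i0 = int(round(s + tmin_s * fs))
        i1 = int(round(s + tmax_s * fs))
        if i0 < 0 or i1 > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, i0:i1])
        conds.append(lb)
    if dropped:
        log.warning("dropped %d epoch(s) overrunning the recording", dropped)
    if not epochs:
        raise NoEvents("all epochs overran the recording")
    data = np.stack(epochs)
    return EpochSet(
        data=data,
        fs_hz=fs,
        t0_offset_s=tmin_s,
        conditions=conds,
        retained=np.ones(len(conds), dtype=bool),
        channel_labels=list(rec.channel_labels),
        metadata={"dropped_boundary": dropped},
    )


def reject_epochs(es: EpochSet, threshold_uv: float) -> tuple[EpochSet, float]:
    """Reject epochs whose absolute amplitude exceeds the threshold anywhere.

    Returns the updated epoch set and the fraction of previously retained
    epochs rejected by this scan.  Idempotent and order-independent.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be > 0")
    peak = np.max(np.abs(es.data), axis=(1, 2))
    ok = peak <= threshold_uv
    before = es.retained.copy()
    retained = before & ok
    n_before = int(before.sum())
    frac = float((n_before - retained.sum()) / n_before) if n_before else 0.0
    out = replace(es, retained=retained, metadata=dict(es.metadata))
    out.metadata["rejected_fraction"] = frac
    return out, frac


def baseline_correct(es: EpochSet, win_start_s: float, win_end_s: float) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    fs = es.fs_hz
    i0 = int(round((win_start_s - es.t0_offset_s) * fs))
    i1 = int(round((win_end_s - es.t0_offset_s) * fs))
    if not (0 <= i0 < i1 <= es.n_samples):
        raise EmptyWindow(f"[{win_start_s}, {win_end_s}) s outside epoch")
    base = es.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(es, data=es.data - base, metadata=dict(es.metadata))
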