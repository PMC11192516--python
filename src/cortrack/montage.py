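"""Schematic 64-channel 10-10 montage used by the synthetic generators.

Coordinates are a flat schematic grid (front = +y), adequate for Delaunay
neighbor finding and for defining smooth topographic gain maps.  They are
not digitized electrode positions.  Two source gain maps are attached:

* ``gain_osc`` — topography of the phase-locked oscillatory response,
  broad with a fronto-central maximum;
* ``gain_erp`` — topography of the semantic-congruency ERP deflection,
  centro-parietal (covering the 14-channel analysis ROI).

Mastoid channels carry no source signal (they serve as the ERP reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingChannel

#: 14 central / centro-posterior channels used for ERP window means.
ROI_CHANNELS = [
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
]

#: Temporal channels with chronically poor contact, excluded before analysis.
NOISY_CHANNELS = ["T7", "T8", "TP7", "TP8"]

#: Mastoid reference channels.
MASTOID_CHANNELS = ["M1", "M2"]

#: Frontal channels dropped as an ocular-artifact guard.
FRONTAL_CHANNELS = ["Fp1", "Fpz", "Fp2"]

#: Compact 16-channel subset (used for scaled-down simulation experiments).
REDUCED_16 = [
    "F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4",
    "CP3", "CPz", "CP4", "P3", "Pz", "P4", "Oz",
]

_ROWS: list[tuple[str, float]] = [
    ("Fp1 Fpz Fp2", 4.0),
    ("AF7 AF3 AFz AF4 AF8", 3.0),
    ("F7 F5 F3 F1 Fz F2 F4 F6 F8", 2.0),
    ("FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8", 1.0),
    ("T7 C5 C3 C1 Cz C2 C4 C6 T8", 0.0),
    ("TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8", -1.0),
    ("P7 P5 P3 P1 Pz P2 P4 P6 P8", -2.0),
    ("PO7 PO3 POz PO4 PO8", -3.0),
    ("O1 Oz O2", -4.0),
    ("Iz", -5.0),
]


@dataclass
class Montage:
    """Channel labels, 2-D layout positions and per-source gain maps."""

    labels: list[str]
    pos: np.ndarray  # (n, 2)
    gain_osc: np.ndarray  # (n,), in [0, 1]
    gain_erp: np.ndarray  # (n,), in [0, 1]
    roi: list[str] = field(default_factory=lambda: list(ROI_CHANNELS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        self.pos = np.asarray(self.pos, dtype=float)
        self.gain_osc = np.asarray(self.gain_osc, dtype=float)
        self.gain_erp = np.asarray(self.gain_erp, dtype=float)
        n = len(self.labels)
        if self.pos.shape != (n, 2):
            raise ValueError("pos must be (n_channels, 2)")
        for g in (self.gain_osc, self.gain_erp):
            if g.shape != (n,) or not np.all(np.isfinite(g)):
                raise ValueError("gain maps must be finite, one per channel")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MissingChannel(label) from None

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.index(lb) for lb in labels]
        roi = [lb for lb in self.roi if lb in labels]
        return Montage(
            labels=list(labels),
            pos=self.pos[idx],
            gain_osc=self.gain_osc[idx],
            gain_erp=self.gain_erp[idx],
            roi=roi,
        )

    @property
    def n_channels(self) -> int:
        return len(self.labels)


def standard_64() -> Montage:
    """Build the default 64-channel schematic montage (62 scalp + 2 mastoids)."""
    labels: list[str] = []
    xy: list[tuple[float, float]] = []
    for row, y in _ROWS:
        names = row.split()
        half = (len(names) - 1) / 2
        for i, name in enumerate(names):
            labels.append(name)
            xy.append((i - half, y))
    labels += MASTOID_CHANNELS
    xy += [(-5.5, -1.0), (5.5, -1.0)]
    pos = np.array(xy, dtype=float)

    def bump(center: tuple[float, float], sigma: float) -> np.ndarray:
        d2 = (pos[:, 0] - center[0]) ** 2 + (pos[:, 1] - center[1]) ** 2
        return np.exp(-d2 / (2 * sigma**2))

    gain_osc = bump((0.0, 0.8), 2.5)
    gain_erp = bump((0.0, -0.9), 2.2)
    for lb in MASTOID_CHANNELS:
        i = labels.index(lb)
        gain_osc[i] = 0.0
        gain_erp[i] = 0.0
    return Montage(labels=labels, pos=pos, gain_osc=gain_osc, gain_erp=gain_erp)
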