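"""Recording/epoch containers, on-disk formats, config and cohort tables.

A recording is stored as three sibling files sharing a stem:

* ``<stem>.json``   — header (fs_hz, channel_labels, units, n_samples,
  dtype ``float32``, little-endian, channel-major);
* ``<stem>.dat``    — raw binary samples;
* ``<stem>.events.tsv`` — events with header ``sample\\tlabel``,
  0-based integer sample indices.

Epoch sets use the same style with a per-epoch TSV (condition, retained).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, UnknownDialect

__all__ = [
    "Recording",
    "write_recording",
    "read_recording",
    "load_config",
    "validate_config",
    "default_config",
    "write_cohort_table",
    "read_cohort_table",
    "validate_cohort_table",
    "dump_json",
]


@dataclass
class Recording:
    """Continuous multi-channel EEG with event markers (units: microvolts)."""

    fs_hz: float
    channel_labels: list[str]
    data: np.ndarray  # (n_channels, n_samples)
    events: list[tuple[int, str]] = field(default_factory=list)
    units: str = "uV"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= int(s) < n:
                raise ValueError(f"event sample {s} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return Recording(
            fs_hz=self.fs_hz,
            channel_labels=list(self.channel_labels),
            data=self.data.copy(),
            events=list(self.events),
            units=self.units,
            metadata=dict(self.metadata),
        )


def write_recording(rec: Recording, stem: str | Path) -> None:
    """Write ``<stem>.json`` + ``<stem>.dat`` + ``<stem>.events.tsv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "fs_hz": rec.fs_hz,
        "channel_labels": rec.channel_labels,
        "units": rec.units,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "byte_order": "little",
        "layout": "channel-major",
        "metadata": _jsonable(rec.metadata),
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))
    rec.data.astype("<f4").tofile(stem.with_suffix(".dat"))
    lines = ["sample\tlabel"] + [f"{int(s)}\t{lb}" for s, lb in rec.events]
    stem.with_suffix(".events.tsv").write_text("\n".join(lines) + "\n")


def read_recording(stem: str | Path) -> Recording:
    """Inverse of :func:`write_recording`; lossless at float32 precision."""
    stem = Path(stem)
    try:
        header = json.loads(stem.with_suffix(".json").read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"bad header JSON: {e}") from e
    if header.get("dtype") != "float32" or header.get("byte_order") != "little":
        raise UnknownDialect(
            f"unsupported dtype/byte order: {header.get('dtype')}/"
            f"{header.get('byte_order')}"
        )
    labels = header["channel_labels"]
    n_samples = int(header["n_samples"])
    raw = np.fromfile(stem.with_suffix(".dat"), dtype="<f4")
    if raw.size != len(labels) * n_samples:
        raise FormatError(
            f"data file has {raw.size} samples, header implies "
            f"{len(labels) * n_samples}"
        )
    data = raw.reshape(len(labels), n_samples).astype(np.float64)
    events: list[tuple[int, str]] = []
    ev_path = stem.with_suffix(".events.tsv")
    lines = ev_path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["sample", "label"]:
        raise FormatError("events TSV must start with 'sample\\tlabel'")
    for ln in lines[1:]:
        if not ln:
            continue
        s_str, label = ln.split("\t", 1)
        s = int(s_str)
        if not 0 <= s < n_samples:
            raise FormatError(f"event sample {s} outside [0, {n_samples})")
        events.append((s, label))
    return Recording(
        fs_hz=float(header["fs_hz"]),
        channel_labels=list(labels),
        data=data,
        events=events,
        units=header.get("units", "uV"),
        metadata=header.get("metadata", {}),
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON report writer (sorted keys, repr floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_epochs(es, stem: str | Path) -> None:
    """Write an EpochSet as header JSON + raw float32 + per-epoch TSV."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "fs_hz": es.fs_hz,
        "t0_offset_s": es.t0_offset_s,
        "channel_labels": es.channel_labels,
        "shape": list(es.data.shape),
        "dtype": "float32",
        "byte_order": "little",
        "layout": "epoch-major",
        "metadata": _jsonable(es.metadata),
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))
    es.data.astype("<f4").tofile(stem.with_suffix(".dat"))
    lines = ["condition\tretained"] + [
        f"{c}\t{int(r)}" for c, r in zip(es.conditions, es.retained)
    ]
    stem.with_suffix(".epochs.tsv").write_text("\n".join(lines) + "\n")


def read_epochs(stem: str | Path):
    """Inverse of :func:`write_epochs`."""
    from .preprocess import EpochSet

    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    if header.get("dtype") != "float32" or header.get("byte_order") != "little":
        raise UnknownDialect(str(header.get("dtype")))
    shape = tuple(int(s) for s in header["shape"])
    raw = np.fromfile(stem.with_suffix(".dat"), dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"data file has {raw.size} values, header implies {np.prod(shape)}"
        )
    lines = stem.with_suffix(".epochs.tsv").read_text().splitlines()
    if not lines or lines[0].split("\t") != ["condition", "retained"]:
        raise FormatError("epochs TSV must start with 'condition\\tretained'")
    conds, retained = [], []
    for ln in lines[1:]:
        if not ln:
            continue
        c, r = ln.split("\t")
        conds.append(c)
        retained.append(bool(int(r)))
    if len(conds) != shape[0]:
        raise FormatError("epochs TSV row count disagrees with header shape")
    return EpochSet(
        data=raw.reshape(shape).astype(np.float64),
        fs_hz=float(header["fs_hz"]),
        t0_offset_s=float(header["t0_offset_s"]),
        conditions=conds,
        retained=np.array(retained, dtype=bool),
        channel_labels=list(header["channel_labels"]),
        metadata=header.get("metadata", {}),
    )


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

_DIST_KEYS = [
    "amp_sentential", "amp_phrasal", "amp_syllabic", "n400_magnitude",
    "noise_scale", "comprehension_rating", "question_accuracy",
    "listening_score",
]

#: required keys: path -> type (dot paths; <group> expands per cohort)
_REQUIRED: dict[str, type | tuple[type, ...]] = {
    "master_seed": int,
    "paradigm": dict,
    "paradigm.syllable_dur_s": (int, float),
    "paradigm.words_per_sentence": int,
    "paradigm.sentences_per_trial": int,
    "paradigm.n_trials": int,
    "paradigm.drop_first_sentence": bool,
    "paradigm.fs_hz": (int, float),
    "montage": dict,
    "entrainment": dict,
    "entrainment.band_hz": list,
    "entrainment.neighbor_k": int,
    "entrainment.alpha": (int, float),
    "n400": dict,
    "n400.band_hz": list,
    "n400.n_sentences_per_condition": int,
    "n400.epoch_s": list,
    "n400.baseline_s": list,
    "n400.reject_uv": (int, float),
    "n400.windows_ms": list,
    "n400.roi": list,
    "n400.fdr_q": (int, float),
    "cohorts": dict,
}


def _get_path(cfg: dict, path: str) -> Any:
    node: Any = cfg
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(path)
        node = node[part]
    return node


def validate_config(cfg: dict) -> dict:
    """Check the config tree; raise :class:`ConfigError` naming the key path."""
    for path, typ in _REQUIRED.items():
        val = _get_path(cfg, path)
        if not isinstance(val, typ):
            raise ConfigError(f"{path} (expected {typ})")
    if not cfg["cohorts"]:
        raise ConfigError("cohorts (at least one group required)")
    for group, gc in cfg["cohorts"].items():
        for key in ("n_subjects", "coupling_rho", "n400_latency_ms",
                    "artifact_rate", "distributions"):
            if key not in gc:
                raise ConfigError(f"cohorts.{group}.{key}")
        for dk in _DIST_KEYS:
            if dk not in gc["distributions"]:
                raise ConfigError(f"cohorts.{group}.distributions.{dk}")
    return cfg


def load_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    return validate_config(cfg)


def default_config() -> dict:
    """The bundled full-scale configuration (two groups of 22 subjects)."""
    from importlib import resources

    text = resources.files("cortrack.configs").joinpath("default.json").read_text()
    return validate_config(json.loads(text))


def small_config() -> dict:
    """A miniature configuration for smoke tests and quick CLI runs."""
    from importlib import resources

    text = resources.files("cortrack.configs").joinpath("small.json").read_text()
    return validate_config(json.loads(text))


# ---------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id", "group", "sentential_db", "phrasal_db", "syllabic_db",
    "n400_300_500_uv", "n400_500_700_uv", "comprehension_rating",
    "question_accuracy", "listening_score",
]


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise FormatError("duplicate subject_id in cohort table")
    if ((df["comprehension_rating"] < 0) | (df["comprehension_rating"] > 4)).any():
        raise FormatError("comprehension_rating outside [0, 4]")
    for col in ("question_accuracy", "listening_score"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise FormatError(f"{col} outside [0, 1]")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path, sep="\t"))
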