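"""Arithmetic of the frequency-tagging paradigm.

Isochronous monosyllabic words are presented at a fixed syllable duration;
pairs of words form phrases and pairs of phrases form sentences, so the
sentential, phrasal and syllabic rhythms appear at exact harmonic rates
(1x, 2x and 4x the inverse sentence duration).  Because an analysis epoch
spans an integer number of sentences, every tagged rate falls exactly on a
DFT bin of the epoch.  This module keeps all of that bookkeeping exact by
carrying durations as rationals until the final float conversion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction

from .errors import MisalignedFrequency, OutOfRange

__all__ = [
    "ParadigmSpec",
    "TagFrequencies",
    "sentence_duration",
    "tag_frequencies",
    "epoch_duration",
    "frequency_resolution",
    "bin_index",
    "neighbor_bins",
    "tag_bins",
    "total_sentences",
]

#: Number of tag levels and their multipliers relative to the sentential rate.
RATE_MULTIPLIERS = {"sentential": 1, "phrasal": 2, "syllabic": 4}


def _frac(x: float) -> Fraction:
    """Best small-denominator rational for a float duration (e.g. 0.32 -> 8/25)."""
    return Fraction(x).limit_denominator(10**6)


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing structure of the entrainment experiment.

    Parameters
    ----------
    syllable_dur_s
        Duration of every (monosyllabic) word, seconds.
    words_per_sentence
        Words per sentence; must be even (phrases are word pairs).
    sentences_per_trial
        Sentences presented back-to-back within one trial.
    n_trials
        Trials per participant.
    drop_first_sentence
        If true, the analysis epoch excludes the first sentence of each
        trial (transient auditory onset response).
    fs_hz
        EEG sampling rate, Hz.
    """

    syllable_dur_s: float = 0.320
    words_per_sentence: int = 4
    sentences_per_trial: int = 12
    n_trials: int = 30
    drop_first_sentence: bool = True
    fs_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.syllable_dur_s <= 0:
            raise ValueError("syllable_dur_s must be > 0")
        if self.words_per_sentence < 2 or self.words_per_sentence % 2:
            raise ValueError("words_per_sentence must be even and >= 2")
        if self.sentences_per_trial < 1:
            raise ValueError("sentences_per_trial must be >= 1")
        if self.drop_first_sentence and self.sentences_per_trial < 2:
            raise ValueError(
                "sentences_per_trial must be >= 2 when drop_first_sentence"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        syllabic = self.words_per_sentence / (
            self.syllable_dur_s * self.words_per_sentence
        )
        if self.fs_hz <= 2 * syllabic:
            raise ValueError("fs_hz must exceed twice the syllabic rate")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParadigmSpec":
        return cls(**json.loads(text))

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmSpec":
        return cls(**d)


@dataclass(frozen=True)
class TagFrequencies:
    """Exact sentential / phrasal / syllabic rates in Hz."""

    sentential_hz: float
    phrasal_hz: float
    syllabic_hz: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Display values, rounded half-to-even at the printed precision."""
        return (
            round(self.sentential_hz, ndigits),
            round(self.phrasal_hz, ndigits),
            round(self.syllabic_hz, ndigits),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "sentential": self.sentential_hz,
            "phrasal": self.phrasal_hz,
            "syllabic": self.syllabic_hz,
        }


# -- exact rational internals ------------------------------------------


def sentence_duration_frac(spec: ParadigmSpec) -> Fraction:
    return _frac(spec.syllable_dur_s) * spec.words_per_sentence


def epoch_duration_frac(spec: ParadigmSpec) -> Fraction:
    n = spec.sentences_per_trial - int(spec.drop_first_sentence)
    return n * sentence_duration_frac(spec)


# -- public operations -------------------------------------------------


def sentence_duration(spec: ParadigmSpec) -> float:
    """Duration of one sentence in seconds (syllable duration x words)."""
    return float(sentence_duration_frac(spec))


def tag_frequencies(spec: ParadigmSpec) -> TagFrequencies:
    """The three tagged rates; phrasal = 2x and syllabic = 4x sentential."""
    base = 1 / sentence_duration_frac(spec)
    return TagFrequencies(
        sentential_hz=float(base),
        phrasal_hz=float(2 * base),
        syllabic_hz=float(4 * base),
    )


def epoch_duration(spec: ParadigmSpec) -> float:
    """Analysis-epoch length in seconds (first sentence optionally dropped)."""
    return float(epoch_duration_frac(spec))


def frequency_resolution(spec: ParadigmSpec) -> float:
    """Spectral resolution of one epoch, 1 / epoch_duration, in Hz."""
    return float(1 / epoch_duration_frac(spec))


def total_sentences(spec: ParadigmSpec) -> int:
    """Sentences presented per participant (before any first-sentence drop)."""
    return spec.n_trials * spec.sentences_per_trial


def bin_index(freq_hz: float, spec: ParadigmSpec, tol: float = 1e-6) -> int:
    """DFT bin of ``freq_hz`` in the epoch spectrum.

    Raises
    ------
    MisalignedFrequency
        If the rate is more than ``tol`` cycles away from an integer bin.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be > 0")
    cycles = freq_hz * epoch_duration(spec)
    b = round(cycles)
    if abs(cycles - b) > tol:
        raise MisalignedFrequency(
            f"{freq_hz} Hz gives {cycles} cycles per epoch; not on a bin"
        )
    return int(b)


def neighbor_bins(bin: int, k: int = 2) -> list[int]:
    """The ``k`` bins on each side of ``bin``, excluding ``bin`` itself."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if bin - k < 1:
        raise OutOfRange(f"bin {bin} has fewer than {k} neighbors below it")
    return list(range(bin - k, bin)) + list(range(bin + 1, bin + k + 1))


def tag_bins(spec: ParadigmSpec, tol: float = 1e-6) -> dict[str, int]:
    """Map rate label -> epoch DFT bin for the three tagged rates."""
    tf = tag_frequencies(spec)
    d = tf.as_dict()
    return {label: bin_index(d[label], spec, tol) for label in RATE_MULTIPLIERS}
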