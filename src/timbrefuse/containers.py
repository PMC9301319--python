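"""Shared in-memory containers: audio stimuli and ordinal rating matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: The four timbre-perception attributes rated by listeners.
ATTRIBUTES = ("fusion", "segregation", "roughness", "pleasantness")

#: Instrument-culture labels for dyad stimuli.
CULTURES = ("Chinese", "Western")

#: Temporal-envelope classes: two sustaining voices (S+S), one sustaining and
#: one non-sustaining (S+N), two non-sustaining (N+N).
ENVELOPE_CLASSES = ("S+S", "S+N", "N+N")


@dataclass
class AudioStimulus:
    """A mono dyad waveform with its stimulus metadata.

    Attributes
    ----------
    samples : float waveform in [-1, 1], mono.
    sample_rate : sampling frequency in Hz.
    stimulus_id : unique identifier within a stimulus set.
    culture : "Chinese" or "Western" (may be empty for ad-hoc audio).
    envelope_class : "S+S", "S+N" or "N+N" (may be empty).
    meta : free-form extras (fundamentals, noise fraction, seed, ...).
    """

    samples: np.ndarray
    sample_rate: int
    stimulus_id: str = ""
    culture: str = ""
    envelope_class: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def write_wav(self, path: str | Path) -> None:
        """Write as 16-bit PCM mono WAV."""
        clipped = np.clip(self.samples, -1.0, 1.0)
        pcm = np.round(clipped * 32767.0).astype(np.int16)
        wavfile.write(str(path), self.sample_rate, pcm)

    @classmethod
    def read_wav(cls, path: str | Path, stimulus_id: str = "") -> "AudioStimulus":
        """Read a PCM WAV; stereo input is downmixed to mono with a warning."""
        sr, data = wavfile.read(str(path))
        if data.ndim == 2:
            import warnings

            warnings.warn(f"{path}: stereo input downmixed to mono")
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
        else:
            data = data.astype(np.float64)
        return cls(samples=data, sample_rate=int(sr),
                   stimulus_id=stimulus_id or Path(path).stem)


class RatingMatrix:
    """Ordinal responses of raters to stimuli on the four attributes.

    Stored long-form with columns ``rater_id, stimulus_id, attribute,
    category``; categories are 1..m (m = 9 by default). After validity
    filtering, imputed categories may be non-integer but stay in [1, m].
    """

    def __init__(self, data: pd.DataFrame, n_categories: int = 9):
        required = {"rater_id", "stimulus_id", "attribute", "category"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"rating table missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.n_categories = int(n_categories)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def raters(self) -> list:
        return sorted(self.data["rater_id"].unique().tolist())

    @property
    def stimuli(self) -> list:
        return sorted(self.data["stimulus_id"].unique().tolist())

    @property
    def attributes(self) -> list:
        return sorted(self.data["attribute"].unique().tolist())

    def pivot(self, attribute: str) -> pd.DataFrame:
        """Stimulus × rater table for one attribute."""
        sub = self.data[self.data["attribute"] == attribute]
        if sub.empty:
            raise KeyError(f"unknown attribute {attribute!r}")
        return sub.pivot(index="stimulus_id", columns="rater_id",
                         values="category")

    def validate(self) -> None:
        cat = self.data["category"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cat)):
            raise ValueError("non-finite rating categories")
        if cat.min() < 1 or cat.max() > self.n_categories:
            raise ValueError(
                f"rating categories outside [1, {self.n_categories}]")

    def is_complete(self) -> bool:
        """True when every (rater, stimulus, attribute) cell is present once."""
        n_expected = (len(self.raters) * len(self.stimuli)
                      * len(self.attributes))
        return len(self.data) == n_expected and not self.data.duplicated(
            ["rater_id", "stimulus_id", "attribute"]).any()

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_categories: int = 9) -> "RatingMatrix":
        return cls(pd.read_csv(path), n_categories=n_categories)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RatingMatrix({len(self.raters)} raters × "
                f"{len(self.stimuli)} stimuli × "
                f"{len(self.attributes)} attributes)")
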