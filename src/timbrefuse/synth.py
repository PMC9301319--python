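"""Synthetic dyad audio and ordinal rating generation.

This module stands in for the listening experiment: it synthesizes
two-voice instrument dyads (additive harmonic voices with sustaining or
non-sustaining energy envelopes plus a controllable broadband noise
fraction) and simulates 9-category ordinal ratings from a Thurstonian
latent-variable model with fixed category boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ATTRIBUTES, CULTURES, ENVELOPE_CLASSES, AudioStimulus, RatingMatrix

# sustaining voices release over this fraction of the total duration;
# non-sustaining voices decay with tau = duration/8, which brings the
# envelope below 10% of peak well before half the note has elapsed
_RELEASE_FRACTION = 0.05
_DECAY_TAU_FRACTION = 1.0 / 8.0


@dataclass
class DyadSpec:
    """Parameters of one synthetic two-voice dyad.

    The two voices are harmonic complexes at fundamentals ``f0_a`` and
    ``f0_b`` (unison or octave by convention) whose partial amplitudes
    decay as ``h ** -spectral_slope``. ``noise_fraction`` is the target
    noise-to-total energy ratio of the mixed signal.
    """

    f0_a: float = 220.0
    f0_b: float = 440.0
    n_harmonics: int = 10
    spectral_slope_a: float = 1.0
    spectral_slope_b: float = 1.0
    noise_fraction: float = 0.0
    envelope_a: str = "sustaining"
    envelope_b: str = "sustaining"
    attack_s: float = 0.02
    duration_s: float = 1.0
    sample_rate: int = 44100
    seed: int = 0

    def validate(self) -> None:
        if self.f0_a <= 0 or self.f0_b <= 0:
            raise ValueError("fundamental frequencies must be positive")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise_fraction must be in [0, 1)")
        if not (self.duration_s > self.attack_s >= 0):
            raise ValueError("need duration_s > attack_s >= 0")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        nyquist = self.sample_rate / 2.0
        if self.n_harmonics * max(self.f0_a, self.f0_b) >= nyquist:
            raise ValueError(
                f"highest harmonic {self.n_harmonics * max(self.f0_a, self.f0_b):.0f} Hz "
                f"at or above Nyquist {nyquist:.0f} Hz")
        for env in (self.envelope_a, self.envelope_b):
            if env not in ("sustaining", "non_sustaining"):
                raise ValueError(f"unknown envelope type {env!r}")

    @property
    def envelope_class(self) -> str:
        n_sus = (self.envelope_a == "sustaining") + (self.envelope_b == "sustaining")
        return {2: "S+S", 1: "S+N", 0: "N+N"}[n_sus]


def _envelope(kind: str, t: np.ndarray, attack_s: float, duration_s: float) -> np.ndarray:
    env = np.ones_like(t)
    if attack_s > 0:
        env = np.minimum(env, t / attack_s)
    if kind == "sustaining":
        release_s = _RELEASE_FRACTION * duration_s
        env = np.minimum(env, np.clip((duration_s - t) / release_s, 0.0, 1.0))
    else:
        tau = _DECAY_TAU_FRACTION * duration_s
        decay = np.exp(-np.maximum(t - attack_s, 0.0) / tau)
        env = env * decay
    return env


def synth_dyad(spec: DyadSpec) -> AudioStimulus:
    """Render one dyad: two enveloped harmonic voices plus broadband noise.

    The noise component is scaled so that its share of the total signal
    energy equals ``spec.noise_fraction`` exactly at synthesis time; the
    result is peak-normalized to 0.9 full scale. Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    voices = np.zeros(n)
    envs = []
    for f0, slope, env_kind in (
        (spec.f0_a, spec.spectral_slope_a, spec.envelope_a),
        (spec.f0_b, spec.spectral_slope_b, spec.envelope_b),
    ):
        env = _envelope(env_kind, t, spec.attack_s, spec.duration_s)
        envs.append(env)
        voice = np.zeros(n)
        for h in range(1, spec.n_harmonics + 1):
            amp = h ** (-slope)
            phase = rng.uniform(0, 2 * np.pi)
            voice += amp * np.sin(2 * np.pi * h * f0 * t + phase)
        voices += env * voice

    harmonic_energy = float(np.sum(voices ** 2))
    if spec.noise_fraction > 0:
        noise = rng.standard_normal(n) * np.maximum(envs[0], envs[1])
        noise_energy = float(np.sum(noise ** 2))
        # solve g so that g^2 En / (g^2 En + Eh) = noise_fraction
        gain = np.sqrt(spec.noise_fraction / (1 - spec.noise_fraction)
                       * harmonic_energy / noise_energy)
        samples = voices + gain * noise
    else:
        samples = voices

    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples * (0.9 / peak)

    return AudioStimulus(
        samples=samples,
        sample_rate=spec.sample_rate,
        envelope_class=spec.envelope_class,
        meta={"f0_a": spec.f0_a, "f0_b": spec.f0_b,
              "noise_fraction": spec.noise_fraction, "seed": spec.seed},
    )


def loudness_normalize(audio: AudioStimulus, target_rms: float = 0.1) -> AudioStimulus:
    """Equalize loudness by scaling the waveform to a target RMS.

    A positive-scalar gain only; the waveform shape is unchanged.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    rms = audio.rms()
    if rms == 0:
        raise ValueError("cannot normalize all-zero audio")
    gain = target_rms / rms
    return AudioStimulus(
        samples=audio.samples * gain,
        sample_rate=audio.sample_rate,
        stimulus_id=audio.stimulus_id,
        culture=audio.culture,
        envelope_class=audio.envelope_class,
        meta=dict(audio.meta),
    )


def default_design() -> dict:
    """Per-culture envelope-class counts of the emulated 518-dyad experiment.

    The totals per class (226 S+S, 227 S+N, 65 N+N; 259 per culture) match
    the study design; the within-culture split of the odd classes is a
    package convention.
    """
    return {
        "Chinese": {"S+S": 113, "S+N": 113, "N+N": 33},
        "Western": {"S+S": 113, "S+N": 114, "N+N": 32},
    }


# fundamentals used when sampling dyad pitches (A2..A4, semitone grid thinned
# to a small pentatonic-ish set; dyads are unison or octave)
_F0_POOL = (110.0, 130.81, 146.83, 164.81, 196.0, 220.0, 261.63, 293.66, 329.63, 392.0)


def build_stimulus_set(
    config: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    duration_s: float = 1.0,
    sample_rate: int = 44100,
    noise_fraction_range: tuple[float, float] = (0.0, 0.4),
) -> tuple[list[AudioStimulus], pd.DataFrame]:
    """Synthesize a full dyad stimulus set from a culture × class design.

    Parameters
    ----------
    config : mapping culture -> {envelope class -> count}. Defaults to the
        518-stimulus design (259 per culture).
    seed : master seed; per-stimulus seeds are derived deterministically.

    Returns
    -------
    (stimuli, metadata) where metadata has one row per stimulus with columns
    ``stimulus_id, culture, envelope_class, f0_a, f0_b, noise_fraction, seed``.
    """
    if config is None:
        config = default_design()
    if not config or all(not cells for cells in config.values()):
        raise ValueError("empty stimulus design")
    for culture, cells in config.items():
        if culture not in CULTURES:
            raise ValueError(f"unknown culture {culture!r}")
        for cls, count in cells.items():
            if cls not in ENVELOPE_CLASSES:
                raise ValueError(f"unknown envelope class {cls!r}")
            if count < 1:
                raise ValueError(f"count for {culture}/{cls} must be >= 1")

    rng = np.random.default_rng(seed)
    env_types = {"S+S": ("sustaining", "sustaining"),
                 "S+N": ("sustaining", "non_sustaining"),
                 "N+N": ("non_sustaining", "non_sustaining")}
    stimuli: list[AudioStimulus] = []
    rows = []
    idx = 0
    for culture in sorted(config):
        for cls in ENVELOPE_CLASSES:
            count = config[culture].get(cls, 0)
            for _ in range(count):
                f0 = float(rng.choice(_F0_POOL))
                octave = bool(rng.integers(0, 2))
                f0_b = f0 * 2 if octave else f0
                nf = float(rng.uniform(*noise_fraction_range))
                env_a, env_b = env_types[cls]
                sub_seed = int(rng.integers(0, 2**31 - 1))
                n_harm = min(12, int((sample_rate / 2 - 1) // max(f0, f0_b)))
                spec = DyadSpec(
                    f0_a=f0, f0_b=f0_b, n_harmonics=max(1, n_harm),
                    spectral_slope_a=float(rng.uniform(0.5, 1.5)),
                    spectral_slope_b=float(rng.uniform(0.5, 1.5)),
                    noise_fraction=nf, envelope_a=env_a, envelope_b=env_b,
                    duration_s=duration_s, sample_rate=sample_rate,
                    seed=sub_seed)
                stim = synth_dyad(spec)
                stim.stimulus_id = f"stim{idx:04d}"
                stim.culture = culture
                stim.envelope_class = cls
                stimuli.append(stim)
                rows.append({"stimulus_id": stim.stimulus_id,
                             "culture": culture, "envelope_class": cls,
                             "f0_a": f0, "f0_b": f0_b,
                             "noise_fraction": nf, "seed": sub_seed})
                idx += 1
    return stimuli, pd.DataFrame(rows)


@dataclass
class LatentPerceptModel:
    """Thurstonian response model used to simulate ordinal ratings.

    Each stimulus has a latent position per attribute: class means are
    planted for fusion and roughness; segregation and pleasantness are
    negatively coupled mirrors of them (``mirrored = pivot +
    coef * (source - pivot) + noise``, ``coef < 0``). A rater's response
    to stimulus *i* is the category *g* whose boundaries bracket
    ``X_i + noise``: ``t_{g-1} < X_i + eps <= t_g`` with ``t_0 = -inf``,
    ``t_m = +inf`` and homoscedastic normal rater noise.

    Default class means follow the observed fusion summaries (S+S 5.97 >
    N+N 5.51 > S+N 3.98) and the reported roughness ordering
    S+S > N+N > S+N; boundaries default to the midpoints 1.5..8.5 so the
    latent scale is in category units.
    """

    class_means: dict = field(default_factory=lambda: {
        "fusion": {"S+S": 5.97, "N+N": 5.51, "S+N": 3.98},
        "roughness": {"S+S": 5.6, "N+N": 4.9, "S+N": 4.3},
    })
    mirror: dict = field(default_factory=lambda: {
        "segregation": ("fusion", -1.0),
        "pleasantness": ("roughness", -1.0),
    })
    mirror_pivot: float = 5.0
    mirror_noise_sd: float = 0.15
    stimulus_sd: float = 0.8
    rater_sd: float = 1.0
    boundaries: np.ndarray = field(
        default_factory=lambda: np.arange(1.5, 9.0, 1.0))
    n_categories: int = 9

    def validate(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) != self.n_categories - 1:
            raise ValueError("need m-1 boundaries for m categories")
        if np.any(np.diff(b) <= 0):
            raise ValueError("category boundaries must be strictly increasing")
        if self.rater_sd <= 0:
            raise ValueError("rater_sd must be positive")
        for attr, (src, coef) in self.mirror.items():
            if coef >= 0:
                raise ValueError(f"mirror coefficient for {attr} must be negative")
            if src not in self.class_means:
                raise ValueError(f"mirror source {src!r} has no class means")

    def latent_values(self, envelope_classes: pd.Series, rng: np.random.Generator
                      ) -> pd.DataFrame:
        """Draw per-stimulus latent positions for all four attributes."""
        self.validate()
        n = len(envelope_classes)
        out = {}
        for attr, means in self.class_means.items():
            mu = envelope_classes.map(means).to_numpy(dtype=float)
            if np.any(np.isnan(mu)):
                bad = envelope_classes[~envelope_classes.isin(means)].unique()
                raise ValueError(f"no class mean for envelope class(es) {bad}")
            out[attr] = mu + rng.normal(0.0, self.stimulus_sd, size=n)
        for attr, (src, coef) in self.mirror.items():
            out[attr] = (self.mirror_pivot + coef * (out[src] - self.mirror_pivot)
                         + rng.normal(0.0, self.mirror_noise_sd, size=n))
        return pd.DataFrame(out, index=envelope_classes.index)


def synth_ratings(
    latent: LatentPerceptModel,
    metadata: pd.DataFrame,
    n_raters: int = 32,
    seed: int = 0,
) -> RatingMatrix:
    """Simulate a complete rating matrix from the latent percept model.

    Every rater rates every stimulus on all four attributes. Deterministic
    given ``seed``; all responses are integers in 1..m.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if "stimulus_id" not in metadata or "envelope_class" not in metadata:
        raise ValueError("metadata needs stimulus_id and envelope_class columns")
    latent.validate()
    rng = np.random.default_rng(seed)
    env = metadata.set_index("stimulus_id")["envelope_class"]
    lat = latent.latent_values(env, rng)

    bounds = np.asarray(latent.boundaries, dtype=float)
    records = []
    rater_ids = [f"r{j:02d}" for j in range(n_raters)]
    for attr in ATTRIBUTES:
        x = lat[attr].to_numpy()[:, None]  # stimuli × 1
        eps = rng.normal(0.0, latent.rater_sd, size=(len(x), n_raters))
        # category = 1 + number of boundaries strictly below the percept
        cats = 1 + np.sum((x + eps)[:, :, None] > bounds[None, None, :], axis=2)
        for si, sid in enumerate(lat.index):
            for rj, rid in enumerate(rater_ids):
                records.append((rid, sid, attr, int(cats[si, rj])))
    df = pd.DataFrame(records,
                      columns=["rater_id", "stimulus_id", "attribute", "category"])
    return RatingMatrix(df, n_categories=latent.n_categories)
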