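"""Objective acoustic descriptor battery for dyad stimuli.

Spectral, harmonic and temporal descriptors in the timbre-toolbox
tradition, computed on a Hann-windowed STFT front end (23.2 ms window,
5.8 ms hop at 44.1 kHz by default), summarized per stimulus as the mean
and interquartile range of 18 frame-varying parameters plus the mean of
9 single-note parameters — a 45-value feature vector — and a screening
step that reduces the full 8-statistic × 27-parameter candidate set
(216) to 54 and then 45.

Conventions (fixed so the numbers are exactly reproducible):

* spectral moments use the per-frame energy probability P(E(n)) =
  |X(n)|^2 / sum |X|^2 on the linear frequency axis;
* roll-off is the smallest frequency containing >= 95% of frame energy;
* flatness is the geometric/arithmetic mean ratio of the power spectrum;
* harmonic partials are per-frame spectral peaks (no single-f0 sieve —
  dyads have two fundamentals); partial energy is the energy in +-3 bins
  around each peak minus the estimated per-bin noise floor, so harmonic
  plus noise energy reproduces total frame energy;
* IQR uses linear-interpolation quartiles; envelope thresholds are
  10%/90% (attack), 40% (effective duration), 50%->5% (release).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import AudioStimulus

# ---------------------------------------------------------------------------
# canonical feature schema

#: frame-varying parameters summarized by mean and IQR (18)
PARAMS_TWO_STAT = (
    "temporal_centroid", "zcr",
    "spectral_centroid", "spectral_spread", "spectral_decrease",
    "spectral_skewness", "spectral_kurtosis", "spectral_rolloff",
    "spectral_flatness", "spectral_crest", "spectral_flux", "rms_energy",
    "harmonic_energy", "noise_energy", "tristimulus",
    "harmonic_deviation", "odd_even_ratio", "noisiness",
)

#: single-note parameters summarized by mean only (9)
PARAMS_MEAN_ONLY = (
    "attack_time", "log_attack_time", "decrease_time", "effective_duration",
    "release_time", "attack_slope", "decrease_slope",
    "frequency_modulation", "amplitude_modulation",
)

#: the 45 canonical feature names
CANONICAL_FEATURES = tuple(
    [f"{p}_{s}" for p in PARAMS_TWO_STAT for s in ("mean", "iqr")]
    + [f"{p}_mean" for p in PARAMS_MEAN_ONLY]
)

#: the 8 frame statistics of the full candidate set
FULL_STATS = ("max", "min", "mean", "var", "std", "iqr", "skew", "kurt")


#: odd-to-even ratio reported when no frame has even-partial energy
ODD_EVEN_CAP = 10.0


def iqr(x: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quartiles."""
    q1, q3 = np.percentile(np.asarray(x, dtype=float), [25, 75])
    return float(q3 - q1)


# ---------------------------------------------------------------------------
# STFT front end


@dataclass
class SpectralFrameSeries:
    """Hann-windowed STFT magnitude frames of one stimulus."""

    times: np.ndarray        # frame centers (s)
    freqs: np.ndarray        # bin frequencies (Hz), one-sided
    magnitudes: np.ndarray   # n_frames × n_bins, >= 0
    sample_rate: int
    n_fft: int
    hop: int

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    def frame_energy(self) -> np.ndarray:
        """Per-frame spectral energy (one-sided, interior bins doubled)."""
        w = np.ones(self.magnitudes.shape[1])
        w[1:] = 2.0
        if self.n_fft % 2 == 0:
            w[-1] = 1.0
        return (self.magnitudes ** 2 * w).sum(axis=1) / self.n_fft

    def energy_prob(self) -> np.ndarray:
        """P(E(n)): per-frame energy probabilities, rows summing to 1.

        All-zero frames yield rows of NaN.
        """
        e = self.magnitudes ** 2
        tot = e.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, e / tot, np.nan)
        return p


def analyze_frames(
    audio: AudioStimulus | np.ndarray,
    sample_rate: int | None = None,
    window_s: float = 0.0232,
    hop_s: float = 0.0058,
) -> SpectralFrameSeries:
    """Compute the Hann STFT magnitude frames of a mono signal."""
    if isinstance(audio, AudioStimulus):
        x, sr = audio.samples, audio.sample_rate
    else:
        x, sr = np.asarray(audio, dtype=float), sample_rate
        if sr is None:
            raise ValueError("sample_rate required for raw arrays")
    n_fft = int(round(window_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    if len(x) < n_fft:
        raise ValueError(f"signal shorter than one window ({n_fft} samples)")
    win = sps.get_window("hann", n_fft, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, n_fft)[::hop]
    mags = np.abs(np.fft.rfft(frames * win, axis=1))
    times = (np.arange(frames.shape[0]) * hop + n_fft / 2) / sr
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    return SpectralFrameSeries(times=times, freqs=freqs, magnitudes=mags,
                               sample_rate=sr, n_fft=n_fft, hop=hop)


# ---------------------------------------------------------------------------
# spectral descriptors


def spectral_descriptors(
    frames: SpectralFrameSeries,
    rolloff_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-frame spectral shape descriptors.

    Returns a DataFrame indexed by frame time with columns
    ``spectral_centroid, spectral_spread, spectral_skewness,
    spectral_kurtosis, spectral_decrease, spectral_rolloff,
    spectral_flatness, spectral_crest, spectral_flux, rms_energy``.
    All-zero frames get NaN descriptors (count available via isna()).
    """
    if frames.n_frames == 0:
        raise ValueError("no frames")
    m = frames.magnitudes
    f = frames.freqs
    p = frames.energy_prob()

    centroid = np.nansum(p * f, axis=1)
    dev = f[None, :] - centroid[:, None]
    spread = np.sqrt(np.nansum(p * dev ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.nansum(p * dev ** 3, axis=1) / spread ** 3
        kurt = np.nansum(p * dev ** 4, axis=1) / spread ** 4

    # spectral decrease: average slope of magnitude relative to the first bin
    k = np.arange(1, m.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        decrease = ((m[:, 1:] - m[:, [0]]) / k).sum(axis=1) / m[:, 1:].sum(axis=1)

    e = m ** 2
    tot = e.sum(axis=1)
    cum = np.cumsum(e, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reached = cum >= rolloff_threshold * tot[:, None]
    roll_idx = np.argmax(reached, axis=1)
    rolloff = f[roll_idx]

    flatness = _band_flatness(e)
    with np.errstate(invalid="ignore", divide="ignore"):
        crest = m.max(axis=1) / m.mean(axis=1)

    norms = np.linalg.norm(m, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, m / norms, np.nan)
    flux = np.zeros(frames.n_frames)
    if frames.n_frames > 1:
        flux[1:] = np.linalg.norm(np.diff(unit, axis=0), axis=1)

    rms = np.sqrt(frames.frame_energy() / frames.n_fft)

    out = pd.DataFrame({
        "spectral_centroid": centroid, "spectral_spread": spread,
        "spectral_skewness": skew, "spectral_kurtosis": kurt,
        "spectral_decrease": decrease, "spectral_rolloff": rolloff,
        "spectral_flatness": flatness, "spectral_crest": crest,
        "spectral_flux": flux, "rms_energy": rms,
    }, index=pd.Index(frames.times, name="time"))
    out[tot == 0] = np.nan
    return out


def _band_flatness(e: np.ndarray, n_bands: int = 32) -> np.ndarray:
    """Spectral flatness as geometric/arithmetic mean ratio over K sub-bands.

    Power is first averaged within K equal-width bands (the sub-band form
    of the flatness measure); a raw-bin ratio would saturate near 0.56 for
    white noise because periodogram bins are exponentially distributed.
    """
    n_bins = e.shape[1]
    n_bands = min(n_bands, n_bins)
    edges = np.linspace(0, n_bins, n_bands + 1).astype(int)
    bands = np.stack([e[:, lo:hi].mean(axis=1)
                      for lo, hi in zip(edges[:-1], edges[1:])], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_b = np.where(bands > 0, np.log(bands), -np.inf)
        geo = np.exp(np.mean(log_b, axis=1))
        return geo / bands.mean(axis=1)


# ---------------------------------------------------------------------------
# harmonic descriptors


@dataclass
class HarmonicFrameSeries:
    """Per-frame detected partials and harmonic/noise energy split."""

    times: np.ndarray
    partial_freqs: list = field(default_factory=list)   # per frame, Hz
    partial_amps: list = field(default_factory=list)    # per frame, energy-consistent amplitudes
    harmonic_energy: np.ndarray | None = None
    noise_energy: np.ndarray | None = None


def harmonic_descriptors(
    frames: SpectralFrameSeries,
    peak_rel_db: float = -50.0,
    lobe_bins: int = 3,
    floor_mult: float = 8.0,
) -> tuple[HarmonicFrameSeries, pd.DataFrame]:
    """Detect partials per frame and derive harmonic-domain descriptors.

    Partials are local spectral maxima within ``peak_rel_db`` of the frame
    maximum that also rise at least ``floor_mult`` times above the frame's
    noise floor (median-based, so harmonic lobes do not inflate it) — the
    floor test keeps random noise maxima from being mistaken for
    partials. Partials are ranked by increasing frequency. Each partial's
    energy is
    the frame energy within +-``lobe_bins`` bins of its peak minus the
    estimated noise-floor share (mean non-peak bin energy), so that
    harmonic energy + noise energy equals total frame energy.

    Returns the partial series and a per-frame descriptor table with
    columns ``harmonic_energy, noise_energy, noisiness, tristimulus,
    tristimulus2, tristimulus3, odd_even_ratio, harmonic_deviation``.
    Frames without detectable partials have harmonic energy 0 and NaN
    partial-ratio descriptors.
    """
    e_frames = frames.magnitudes ** 2
    # one-sided energy weighting so splits sum to the true frame energy
    w = np.ones(frames.magnitudes.shape[1])
    w[1:] = 2.0
    if frames.n_fft % 2 == 0:
        w[-1] = 1.0
    e_frames = e_frames * w / frames.n_fft

    series = HarmonicFrameSeries(times=frames.times)
    n_bins = e_frames.shape[1]
    cols = {name: np.full(frames.n_frames, np.nan) for name in
            ("harmonic_energy", "noise_energy", "noisiness", "tristimulus",
             "tristimulus2", "tristimulus3", "odd_even_ratio",
             "harmonic_deviation")}

    for i in range(frames.n_frames):
        mag = frames.magnitudes[i]
        e = e_frames[i]
        total = e.sum()
        if total == 0:
            series.partial_freqs.append(np.array([]))
            series.partial_amps.append(np.array([]))
            cols["harmonic_energy"][i] = 0.0
            cols["noise_energy"][i] = 0.0
            continue
        height = mag.max() * 10 ** (peak_rel_db / 20)
        peaks, _ = sps.find_peaks(mag, height=height)
        if len(peaks):
            # robust noise-floor estimate: the median energy bin sits in the
            # noise field (harmonic lobes occupy a minority of bins), and for
            # exponentially distributed noise bins mean = median / ln 2
            floor = np.median(e) / np.log(2.0)
            peaks = peaks[e[peaks] > floor_mult * floor]
        if len(peaks) == 0:
            series.partial_freqs.append(np.array([]))
            series.partial_amps.append(np.array([]))
            cols["harmonic_energy"][i] = 0.0
            cols["noise_energy"][i] = total
            cols["noisiness"][i] = 1.0
            continue

        harm_mask = np.zeros(n_bins, dtype=bool)
        for pk in peaks:
            harm_mask[max(0, pk - lobe_bins):pk + lobe_bins + 1] = True
        n_noise_bins = int((~harm_mask).sum())
        noise_per_bin = (e[~harm_mask].mean() if n_noise_bins > 0 else 0.0)
        # each masked bin contributes to its nearest peak only, so closely
        # spaced partials with overlapping lobes are not double-counted
        masked_bins = np.flatnonzero(harm_mask)
        nearest = np.argmin(np.abs(masked_bins[:, None] - peaks[None, :]),
                            axis=1)
        p_energy = np.zeros(len(peaks))
        np.add.at(p_energy, nearest, e[masked_bins])
        bin_counts = np.bincount(nearest, minlength=len(peaks))
        p_energy = np.maximum(p_energy - noise_per_bin * bin_counts, 0.0)
        harm_total = float(p_energy.sum())
        noise_est = min(max(total - harm_total, 0.0), total)

        amps = np.sqrt(p_energy)
        series.partial_freqs.append(frames.freqs[peaks])
        series.partial_amps.append(amps)

        cols["harmonic_energy"][i] = harm_total
        cols["noise_energy"][i] = noise_est
        cols["noisiness"][i] = noise_est / total
        if harm_total > 0:
            pe = p_energy / harm_total
            cols["tristimulus"][i] = pe[0]
            cols["tristimulus2"][i] = pe[1:4].sum()
            cols["tristimulus3"][i] = pe[4:].sum()
            odd = p_energy[0::2].sum()   # partials 1, 3, 5, ...
            even = p_energy[1::2].sum()  # partials 2, 4, ...
            cols["odd_even_ratio"][i] = odd / even if even > 0 else np.nan
            if len(amps) >= 3:
                smooth = np.convolve(amps, np.ones(3) / 3, mode="same")
                smooth[0] = (amps[0] + amps[1]) / 2
                smooth[-1] = (amps[-2] + amps[-1]) / 2
                with np.errstate(invalid="ignore", divide="ignore"):
                    cols["harmonic_deviation"][i] = float(
                        np.mean(np.abs(amps - smooth)) / np.mean(amps))
            else:
                cols["harmonic_deviation"][i] = 0.0

    series.harmonic_energy = cols["harmonic_energy"]
    series.noise_energy = cols["noise_energy"]
    table = pd.DataFrame(cols, index=pd.Index(frames.times, name="time"))
    return series, table


# ---------------------------------------------------------------------------
# temporal descriptors


def energy_envelope(x: np.ndarray, sr: int, cutoff_hz: float = 20.0) -> np.ndarray:
    """Amplitude envelope: rectification followed by zero-phase low-pass."""
    b, a = sps.butter(3, cutoff_hz / (sr / 2), btype="low")
    env = sps.filtfilt(b, a, np.abs(x))
    return np.maximum(env, 0.0)


def temporal_descriptors(audio: AudioStimulus) -> dict:
    """Whole-note temporal descriptors from the energy envelope.

    Thresholds: attack spans 10%->90% of the envelope peak; decrease time
    runs from the peak to the last point above 10%; release from the last
    point above 50% to the last above 5%; effective duration is the span
    above 40%. ZCR is in crossings per second; AM is the relative envelope
    fluctuation depth in the 4-8 Hz band over the sustained (>= 50%)
    segment; FM is the standard deviation (Hz) of the lowest-partial
    frequency track over energetic frames.
    """
    x = audio.samples
    sr = audio.sample_rate
    if np.all(x == 0):
        raise ValueError("silent input")
    t = np.arange(len(x)) / sr
    env = energy_envelope(x, sr)
    peak = env.max()

    above10 = np.flatnonzero(env >= 0.1 * peak)
    above90 = np.flatnonzero(env >= 0.9 * peak)
    t10, t90 = t[above10[0]], t[above90[0]]
    attack = max(t90 - t10, 1.0 / sr)
    i_peak = int(np.argmax(env))
    decrease_time = max(t[above10[-1]] - t[i_peak], 0.0)

    above50 = np.flatnonzero(env >= 0.5 * peak)
    above5 = np.flatnonzero(env >= 0.05 * peak)
    release_time = max(t[above5[-1]] - t[above50[-1]], 0.0)

    above40 = np.flatnonzero(env >= 0.4 * peak)
    effective_duration = t[above40[-1]] - t[above40[0]]

    e2 = env ** 2
    temporal_centroid = float(np.sum(t * e2) / np.sum(e2))

    attack_slope = 0.8 * peak / attack
    # decrease slope: log-envelope fit from the peak to the last >= 10% point
    seg = slice(i_peak, above10[-1] + 1)
    if above10[-1] > i_peak + 1:
        logenv = np.log(np.maximum(env[seg], 1e-12 * peak))
        decrease_slope = float(np.polyfit(t[seg], logenv, 1)[0])
    else:
        decrease_slope = 0.0

    zcr = float(np.sum(np.abs(np.diff(np.signbit(x)))) / (len(x) / sr))

    # AM: 4-8 Hz band of the envelope over the sustained segment
    sus = slice(above50[0], above50[-1] + 1)
    am = 0.0
    if above50[-1] - above50[0] > sr // 2:
        b, a = sps.butter(2, [4 / (sr / 2), 8 / (sr / 2)], btype="band")
        bp = sps.filtfilt(b, a, env)[sus]
        am = float(2.0 * np.std(bp) / np.mean(env[sus]))

    fm = _frequency_modulation(audio)

    return {
        "attack_time": float(attack),
        "log_attack_time": float(np.log10(attack)),
        "decrease_time": float(decrease_time),
        "effective_duration": float(effective_duration),
        "release_time": float(release_time),
        "attack_slope": float(attack_slope),
        "decrease_slope": float(decrease_slope),
        "temporal_centroid": temporal_centroid,
        "zcr": zcr,
        "amplitude_modulation": am,
        "frequency_modulation": fm,
    }


def _frequency_modulation(audio: AudioStimulus) -> float:
    """SD (Hz) of the lowest detected partial's frequency over strong frames."""
    try:
        frames = analyze_frames(audio)
    except ValueError:
        return 0.0
    e = frames.frame_energy()
    strong = e >= 0.1 * e.max()
    track = []
    for i in np.flatnonzero(strong):
        mag = frames.magnitudes[i]
        peaks, _ = sps.find_peaks(mag, height=mag.max() * 10 ** (-30 / 20))
        if len(peaks):
            pk = peaks[0]
            # parabolic interpolation for sub-bin resolution
            if 0 < pk < len(mag) - 1:
                a, b, c = mag[pk - 1], mag[pk], mag[pk + 1]
                denom = a - 2 * b + c
                delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
            else:
                delta = 0.0
            track.append((pk + delta) * frames.sample_rate / frames.n_fft)
    if len(track) < 2:
        return 0.0
    return float(np.std(track))


def frame_temporal_series(
    audio: AudioStimulus,
    frames: SpectralFrameSeries,
) -> pd.DataFrame:
    """Per-frame ZCR (crossings/s) and local temporal centroid (s).

    The local temporal centroid is the energy-weighted mean time within
    each analysis window, measured from the window start.
    """
    x = audio.samples
    n_fft, hop = frames.n_fft, frames.hop
    windows = np.lib.stride_tricks.sliding_window_view(x, n_fft)[::hop]
    windows = windows[:frames.n_frames]
    sr = frames.sample_rate

    crossings = np.abs(np.diff(np.signbit(windows), axis=1)).sum(axis=1)
    zcr = crossings / (n_fft / sr)

    tloc = np.arange(n_fft) / sr
    e = windows ** 2
    tot = e.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(tot > 0, (e * tloc).sum(axis=1) / tot, np.nan)
    return pd.DataFrame({"zcr": zcr, "temporal_centroid": tc},
                        index=pd.Index(frames.times[:len(zcr)], name="time"))


# ---------------------------------------------------------------------------
# summary and screening


@dataclass
class FeatureVector:
    """The 45 canonical acoustic statistics of one stimulus."""

    values: dict
    stimulus_id: str = ""

    def __post_init__(self):
        missing = set(CANONICAL_FEATURES) - set(self.values)
        extra = set(self.values) - set(CANONICAL_FEATURES)
        if missing or extra:
            raise ValueError(
                f"feature vector schema mismatch: missing={sorted(missing)}, "
                f"extra={sorted(extra)}")

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in CANONICAL_FEATURES},
                         name=self.stimulus_id or None)


def summarize_features(
    frame_table: pd.DataFrame,
    temporal: dict,
) -> FeatureVector:
    """Reduce per-frame series and single-note scalars to the 45-value vector.

    ``frame_table`` must contain one column per two-statistic parameter;
    invalid (NaN) frames are excluded per column. ``temporal`` supplies the
    nine single-note scalars.
    """
    values = {}
    for p in PARAMS_TWO_STAT:
        if p not in frame_table.columns:
            raise KeyError(f"missing frame series {p!r}")
        series = frame_table[p].dropna().to_numpy()
        if len(series) == 0:
            if p == "odd_even_ratio":
                # all-odd spectra (e.g. a lone partial) leave the ratio
                # undefined in every frame; cap it at a fixed large value
                values[f"{p}_mean"] = ODD_EVEN_CAP
                values[f"{p}_iqr"] = 0.0
                continue
            raise ValueError(f"no valid frames for {p!r}")
        values[f"{p}_mean"] = float(np.mean(series))
        values[f"{p}_iqr"] = iqr(series)
    for p in PARAMS_MEAN_ONLY:
        values[f"{p}_mean"] = float(temporal[p])
    return FeatureVector(values=values)


def extract_features(
    audio: AudioStimulus,
    window_s: float = 0.0232,
    hop_s: float = 0.0058,
    full_stats: bool = False,
) -> FeatureVector | tuple[FeatureVector, pd.Series]:
    """Full per-stimulus extraction: STFT, descriptors, 45-value summary.

    With ``full_stats=True`` also returns the 216-statistic candidate
    vector (8 statistics × 27 parameters) used by :func:`screen_features`.
    """
    frames = analyze_frames(audio, window_s=window_s, hop_s=hop_s)
    spec = spectral_descriptors(frames)
    _, harm = harmonic_descriptors(frames)
    temporal = temporal_descriptors(audio)
    ft = frame_temporal_series(audio, frames)
    frame_table = pd.concat(
        [ft, spec, harm.drop(columns=["tristimulus2", "tristimulus3"])],
        axis=1)
    fv = summarize_features(frame_table, temporal)
    fv.stimulus_id = audio.stimulus_id
    if not full_stats:
        return fv
    return fv, full_statistics(frame_table, temporal)


def full_statistics(frame_table: pd.DataFrame, temporal: dict) -> pd.Series:
    """The 216-statistic candidate set: 8 statistics × 27 parameters.

    Frame-varying parameters use their per-frame series; single-note
    parameters enter as degenerate constant series (their spread
    statistics are zero and are dropped as uninformative during
    screening).
    """
    from scipy import stats as sci_stats

    def stat_row(x: np.ndarray) -> dict:
        if len(x) == 0:
            return {s: np.nan for s in FULL_STATS}
        return {
            "max": float(np.max(x)), "min": float(np.min(x)),
            "mean": float(np.mean(x)), "var": float(np.var(x, ddof=1)) if len(x) > 1 else 0.0,
            "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "iqr": iqr(x),
            "skew": float(sci_stats.skew(x)) if len(x) > 2 else 0.0,
            "kurt": float(sci_stats.kurtosis(x)) if len(x) > 3 else 0.0,
        }

    out = {}
    for p in PARAMS_TWO_STAT:
        row = stat_row(frame_table[p].dropna().to_numpy())
        for s, v in row.items():
            out[f"{p}_{s}"] = v
    for p in PARAMS_MEAN_ONLY:
        row = stat_row(np.array([temporal[p]]))
        row.update({"var": 0.0, "std": 0.0, "iqr": 0.0, "skew": 0.0, "kurt": 0.0})
        for s, v in row.items():
            out[f"{p}_{s}"] = v
    return pd.Series(out)


def screen_features(
    full_stats_table: pd.DataFrame,
    target: np.ndarray,
) -> tuple[list[str], pd.DataFrame]:
    """Screen the 216-statistic candidate set down to the canonical 45.

    Computes |Pearson r| of every candidate statistic against the target
    (constant candidates are dropped with a warning), reports the ranking
    grouped by statistic family, and applies the retention rule: keep the
    mean and IQR families (54 statistics), then drop the IQR of the nine
    single-note parameters, leaving the canonical 45.

    Returns (retained names, ranking table with columns
    ``parameter, statistic, abs_r``).
    """
    import warnings

    y = np.asarray(target, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target")

    rows = []
    for col in full_stats_table.columns:
        x = full_stats_table[col].to_numpy(dtype=float)
        param, stat = col.rsplit("_", 1)
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            warnings.warn(f"constant or invalid candidate {col!r} dropped")
            r = np.nan
        else:
            r = abs(np.corrcoef(x, y)[0, 1])
        rows.append({"parameter": param, "statistic": stat, "abs_r": r})
    ranking = pd.DataFrame(rows).sort_values(
        "abs_r", ascending=False, na_position="last").reset_index(drop=True)

    retained_54 = [f"{p}_{s}" for p in PARAMS_TWO_STAT + PARAMS_MEAN_ONLY
                   for s in ("mean", "iqr")]
    retained = [c for c in retained_54
                if not (c.endswith("_iqr")
                        and c[:-4] in PARAMS_MEAN_ONLY)]
    assert len(retained_54) == 54 and len(retained) == 45
    return retained, ranking


def features_frame(stimuli: list[AudioStimulus], **kwargs) -> pd.DataFrame:
    """Extract the 45-column feature table for a list of stimuli."""
    rows = {}
    for stim in stimuli:
        rows[stim.stimulus_id] = extract_features(stim, **kwargs).to_series()
    df = pd.DataFrame(rows).T
    df.index.name = "stimulus_id"
    return df[list(CANONICAL_FEATURES)]
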