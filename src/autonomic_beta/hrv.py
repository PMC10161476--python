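"""Time- and frequency-domain heart-rate-variability analysis of 24-h beat series.

The entry point is a labelled beat series (one row per heartbeat: time in
seconds from recording start plus a sinus / ectopic / artifact label, as a
Holter analysis system would emit after QRS classification).  From it the
module derives the normal-to-normal (NN) interval series and computes the
standard long-term HRV indices:

* time domain — SDNN, SDANN, RMSSD, SDNN index, NN50, pNN50, SDSD;
* frequency domain — total power and the ULF / VLF / LF / HF band powers of
  the NN tachogram, from a single full-record FFT periodogram.

Cohort-level composite z-scores (the mean of the five z-scored indices per
domain) are computed by :func:`hrv_composites`.

Conventions (documented, applied consistently):

* all standard deviations use the sample (n-1) denominator;
* NN50 counts successive differences with ``|dNN| > 50 ms`` (strict);
* pNN50 divides NN50 by the *total* NN-interval count;
* successive-difference statistics (RMSSD, NN50, SDSD) never span a gap left
  by an excluded non-sinus beat;
* SDSD is reported equal to RMSSD;
* recordings with less than 18 h of retained sinus data are unusable for
  24-h HRV and are flagged by :func:`check_duration`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline

__all__ = [
    "BeatSeries",
    "NNSeries",
    "extract_nn",
    "check_duration",
    "time_domain",
    "frequency_domain",
    "analyze_beats",
    "hrv_composites",
    "read_beat_file",
    "TIME_DOMAIN_COMPOSITE",
    "FREQUENCY_DOMAIN_COMPOSITE",
    "MIN_RECORDING_HOURS",
]

SINUS, ECTOPIC, ARTIFACT = "N", "E", "A"
VALID_LABELS = frozenset({SINUS, ECTOPIC, ARTIFACT})

#: Minimum retained sinus coverage for a usable 24-h HRV analysis (hours).
MIN_RECORDING_HOURS = 18.0

#: Index sets entering the two composite z-scores.
TIME_DOMAIN_COMPOSITE = ("sdnn_ms", "rmssd_ms", "sdann_ms", "sdnn_index_ms", "pnn50_pct")
FREQUENCY_DOMAIN_COMPOSITE = ("tp_ms2", "ulf_ms2", "vlf_ms2", "lf_ms2", "hf_ms2")

#: Spectral band edges in Hz, half-open [lo, hi); ULF is (0, 0.003).
BANDS = {
    "ulf_ms2": (0.0, 0.003),
    "vlf_ms2": (0.003, 0.04),
    "lf_ms2": (0.04, 0.15),
    "hf_ms2": (0.15, 0.4),
}
TP_UPPER_HZ = 0.4

SEGMENT_S = 300.0  # 5-minute segments for SDANN / SDNN index


@dataclass(frozen=True)
class BeatSeries:
    """Timestamped heartbeats with sinus / ectopic / artifact labels."""

    beat_time_s: np.ndarray
    label: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_time_s, dtype=float)
        lab = np.asarray(self.label, dtype=object)
        if t.ndim != 1 or t.shape != lab.shape:
            raise ValueError("beat_time_s and label must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        unknown = set(np.unique(lab)) - VALID_LABELS
        if unknown:
            raise ValueError(f"unknown beat labels: {sorted(unknown)}")
        object.__setattr__(self, "beat_time_s", t)
        object.__setattr__(self, "label", lab)

    @property
    def n_beats(self) -> int:
        return int(self.beat_time_s.size)

    @property
    def recording_duration_h(self) -> float:
        if self.n_beats < 2:
            return 0.0
        return float(self.beat_time_s[-1] - self.beat_time_s[0]) / 3600.0


@dataclass(frozen=True)
class NNSeries:
    """Normal-to-normal intervals retained from a beat series.

    ``onset_time_s`` is the time of the beat opening each interval;
    ``run_id`` indexes maximal contiguous runs of retained intervals
    (successive-difference statistics stay within a run);
    ``segment_index`` is the 5-minute bin of the recording clock.
    """

    nn_ms: np.ndarray
    onset_time_s: np.ndarray
    run_id: np.ndarray
    segment_index: np.ndarray
    effective_duration_h: float

    @property
    def n_intervals(self) -> int:
        return int(self.nn_ms.size)


def extract_nn(beats: BeatSeries) -> NNSeries:
    """Derive the NN-interval series, excluding non-sinus cardiac cycles.

    An interbeat interval is retained only when both delimiting beats are
    sinus; every interval touching an ectopic or artifact beat is dropped, so
    a single non-sinus beat removes its two flanking intervals.  Effective
    duration is the summed length of retained intervals.
    """
    if beats.n_beats < 2:
        raise ValueError("need at least two beats to form intervals")
    t = beats.beat_time_s
    sinus = beats.label == SINUS
    keep = sinus[:-1] & sinus[1:]
    if not keep.any():
        raise ValueError("no NN intervals retained: recording unusable")
    dt_s = np.diff(t)[keep]
    onset = t[:-1][keep]
    # a new contiguous run starts wherever the previous interval was dropped
    keep_idx = np.flatnonzero(keep)
    run_id = np.concatenate([[0], np.cumsum(np.diff(keep_idx) != 1)])
    segment_index = np.floor_divide(onset - t[0], SEGMENT_S).astype(int)
    return NNSeries(
        nn_ms=dt_s * 1000.0,
        onset_time_s=onset,
        run_id=run_id,
        segment_index=segment_index,
        effective_duration_h=float(dt_s.sum()) / 3600.0,
    )


def check_duration(nn: NNSeries, min_hours: float = MIN_RECORDING_HOURS) -> bool:
    """True when retained sinus coverage meets the minimum (boundary inclusive)."""
    return nn.effective_duration_h >= min_hours


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def _successive_diffs(nn: NNSeries) -> np.ndarray:
    """Differences of adjacent NN intervals, never spanning an excluded gap."""
    within = np.diff(nn.run_id) == 0
    return np.diff(nn.nn_ms)[within]


def time_domain(nn: NNSeries) -> dict:
    """SDNN, SDANN, RMSSD, SDNN index, NN50, pNN50 and SDSD for one subject.

    SDANN and the SDNN index summarise 5-min segments of the recording clock;
    SDANN needs at least two segments and is reported missing otherwise.
    """
    if nn.n_intervals < 2:
        raise ValueError("need at least two NN intervals")
    out: dict = {}
    out["sdnn_ms"] = _sample_sd(nn.nn_ms)

    seg = pd.Series(nn.nn_ms).groupby(nn.segment_index)
    seg_means = seg.mean()
    if len(seg_means) >= 2:
        out["sdann_ms"] = float(seg_means.std(ddof=1))
    else:
        out["sdann_ms"] = np.nan
    seg_sds = seg.std(ddof=1).dropna()
    out["sdnn_index_ms"] = float(seg_sds.mean()) if len(seg_sds) else np.nan

    d = _successive_diffs(nn)
    if d.size:
        out["rmssd_ms"] = float(np.sqrt(np.mean(d**2)))
        out["nn50_count"] = int(np.sum(np.abs(d) > 50.0))
    else:
        out["rmssd_ms"] = np.nan
        out["nn50_count"] = 0
    out["pnn50_pct"] = 100.0 * out["nn50_count"] / nn.n_intervals
    out["sdsd_ms"] = out["rmssd_ms"]
    return out


def _resample_tachogram(nn: NNSeries, fs_hz: float, interp: str = "cubic") -> np.ndarray:
    """NN tachogram interpolated onto an even grid (gaps bridged).

    Cubic-spline interpolation (default) is amplitude-faithful for
    oscillations up to the HF band at typical heart rates; linear
    interpolation attenuates HF-band power noticeably and is kept only as
    a selectable alternative.
    """
    # tachogram sample: interval length attributed to the interval's onset
    t = nn.onset_time_s - nn.onset_time_s[0]
    if t[-1] <= 0:
        raise ValueError("cannot resample a degenerate tachogram")
    grid = np.arange(0.0, t[-1], 1.0 / fs_hz)
    if interp == "linear":
        return np.interp(grid, t, nn.nn_ms)
    if interp == "cubic":
        return CubicSpline(t, nn.nn_ms)(grid)
    raise ValueError(f"unknown interpolation {interp!r}")


def frequency_domain(
    nn: NNSeries,
    fs_hz: float = 4.0,
    min_hours: float = MIN_RECORDING_HOURS,
    interp: str = "cubic",
) -> dict:
    """Band powers of the NN tachogram from a single full-record periodogram.

    The tachogram is resampled to ``fs_hz`` (default 4 Hz) by cubic-spline
    interpolation (``interp="linear"`` selectable), mean-detrended, Hann-windowed and Fourier-transformed in
    one segment; Welch averaging is deliberately not used because the ULF
    band needs full-record frequency resolution.  The periodogram is
    normalised so that its integral equals the variance of the detrended
    tachogram (power in ms^2).  Total power integrates frequencies up to
    0.4 Hz; bands are half-open ``[lo, hi)`` with ULF = (0, 0.003) Hz.
    """
    if nn.effective_duration_h < min_hours:
        raise ValueError(
            f"frequency-domain analysis needs >= {min_hours} h of sinus data "
            f"(got {nn.effective_duration_h:.2f} h)"
        )
    x = _resample_tachogram(nn, fs_hz, interp=interp)
    freqs, psd = sp_signal.periodogram(
        x, fs=fs_hz, window="hann", detrend="constant", scaling="density"
    )
    df = freqs[1] - freqs[0]
    out: dict = {}
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
        out[name] = float(np.sum(psd[mask]) * df)
    tp_mask = (freqs > 0) & (freqs <= TP_UPPER_HZ)
    out["tp_ms2"] = float(np.sum(psd[tp_mask]) * df)
    return out


def analyze_beats(
    beats: BeatSeries,
    min_hours: float = MIN_RECORDING_HOURS,
    fs_hz: float = 4.0,
) -> dict | None:
    """Full single-subject HRV profile, or None when the recording is too short."""
    nn = extract_nn(beats)
    if not check_duration(nn, min_hours):
        return None
    profile = time_domain(nn)
    profile.update(frequency_domain(nn, fs_hz=fs_hz, min_hours=min_hours))
    return profile


def hrv_composites(profiles: pd.DataFrame) -> pd.DataFrame:
    """Cohort composite z-scores for the time and frequency domains.

    Each index is z-scored against the analysis sample (sample SD), and each
    domain composite is the mean of its five index z-scores:
    (SDNN + RMSSD + SDANN + SDNN index + pNN50) / 5 and
    (TP + ULF + VLF + LF + HF) / 5.
    """
    if len(profiles) < 2:
        raise ValueError("composites need at least two subjects")
    out = profiles.copy()
    for name, cols in (
        ("hrv_time_z", TIME_DOMAIN_COMPOSITE),
        ("hrv_freq_z", FREQUENCY_DOMAIN_COMPOSITE),
    ):
        z = []
        for col in cols:
            sd = profiles[col].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"index {col} has zero variance across the cohort")
            z.append((profiles[col] - profiles[col].mean()) / sd)
        out[name] = sum(z) / len(z)
    return out


def read_beat_file(path, subject_id: str = "") -> BeatSeries:
    """Read a whitespace-delimited beat file: columns beat_time_s, label (N/E/A)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["beat_time_s", "label"])
    return BeatSeries(
        beat_time_s=df["beat_time_s"].to_numpy(float),
        label=df["label"].astype(str).str.strip().to_numpy(object),
        subject_id=subject_id,
    )
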