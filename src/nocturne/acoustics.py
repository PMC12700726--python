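"""Acoustic Complexity Index (ACI) from night soundscape recordings.

The ACI summarises how much spectral power fluctuates between adjacent
time frames: biotic transients (calls) produce large frame-to-frame
changes, while steady noise (wind, rain hiss at constant level) does not.
The variant implemented here normalises every adjacent-frame pair by the
summed power of that pair,

    ACI = sum_f sum_i |P(f, t_i) - P(f, t_{i-1})| / (P(f, t_i) + P(f, t_{i-1})),

accumulated per 600-s window over a band-limited power spectrogram and
summed over windows for a whole-file total.  The classical Pieretti
normalisation (per-window total intensity per frequency bin) is available
behind ``classical=True`` for comparison.

Silence is defined to contribute nothing: a pair with zero summed power
adds 0 to the sum, which keeps the index finite and monotone in signal
presence.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import stft

__all__ = [
    "PowerSpectrogram",
    "AciWindow",
    "HourlyAci",
    "read_wav",
    "compute_power_spectrogram",
    "band_limit",
    "aci_value",
    "aci_windows",
    "hourly_aci",
]


@dataclass
class PowerSpectrogram:
    """Nonnegative spectral power on a frequency x time grid.

    Parameters
    ----------
    power : (n_freq, n_time) array of relative power values, >= 0.
    freq_edges : (n_freq, 2) array of lower/upper bin edges in Hz,
        strictly increasing and non-overlapping.
    time_step : seconds between adjacent columns.
    start_time : wall-clock timestamp of the first column, or None.
    """

    power: np.ndarray
    freq_edges: np.ndarray
    time_step: float
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freq_edges = np.asarray(self.freq_edges, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be a 2-D (freq x time) array")
        if self.freq_edges.shape != (self.power.shape[0], 2):
            raise ValueError("freq_edges must be (n_freq, 2)")
        if np.any(self.power < 0):
            raise ValueError("power values must be nonnegative")
        lo, hi = self.freq_edges[:, 0], self.freq_edges[:, 1]
        if np.any(hi <= lo):
            raise ValueError("each frequency bin needs upper edge > lower edge")
        if np.any(lo[1:] < hi[:-1] - 1e-9):
            raise ValueError("frequency bins must be increasing and non-overlapping")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def n_freq(self) -> int:
        return self.power.shape[0]

    @property
    def n_times(self) -> int:
        return self.power.shape[1]


@dataclass(frozen=True)
class AciWindow:
    """ACI of one analysis window (600 s by default)."""

    window_index: int
    start_time: datetime | None
    aci: float
    n_cols: int


@dataclass(frozen=True)
class HourlyAci:
    """Mean window ACI within one clock hour."""

    hour: int
    aci: float
    n_windows: int


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file to a mono float waveform in [-1, 1].

    Stereo input is downmixed by channel averaging; integer PCM is scaled
    by its full-scale value.
    """
    sample_rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return data, int(sample_rate)


def compute_power_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    frame_length: int = 1024,
    hop: int = 512,
    window: str = "hann",
    start_time: datetime | None = None,
) -> PowerSpectrogram:
    """Short-time power spectrogram (squared STFT magnitude per frame).

    No padding is applied, so the column count is
    ``floor((n_samples - frame_length) / hop) + 1``.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if waveform.size == 0:
        raise ValueError("empty audio")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if frame_length < 2:
        raise ValueError("frame_length must be >= 2")
    if not 0 < hop:
        raise ValueError("hop must be positive")
    if waveform.size < frame_length:
        raise ValueError("audio shorter than one frame")
    freqs, _, z = stft(
        waveform,
        fs=sample_rate,
        window=window,
        nperseg=frame_length,
        noverlap=frame_length - hop,
        boundary=None,
        padded=False,
        detrend=False,
    )
    power = np.abs(z) ** 2
    df = sample_rate / frame_length
    lo = np.maximum(freqs - df / 2.0, 0.0)
    hi = freqs + df / 2.0
    edges = np.column_stack([lo, hi])
    return PowerSpectrogram(
        power=power, freq_edges=edges, time_step=hop / sample_rate, start_time=start_time
    )


def band_limit(spec: PowerSpectrogram, f_min: float, f_max: float) -> PowerSpectrogram:
    """Keep only frequency rows whose bin overlaps [f_min, f_max]."""
    if f_min >= f_max:
        raise ValueError("f_min must be < f_max")
    lo, hi = spec.freq_edges[:, 0], spec.freq_edges[:, 1]
    keep = (hi > f_min) & (lo < f_max)
    if not np.any(keep):
        raise ValueError("empty band: no frequency bins overlap the requested range")
    return PowerSpectrogram(
        power=spec.power[keep],
        freq_edges=spec.freq_edges[keep],
        time_step=spec.time_step,
        start_time=spec.start_time,
    )


def aci_value(spec: PowerSpectrogram, classical: bool = False) -> float:
    """ACI of a whole spectrogram treated as one window.

    Each adjacent column pair contributes |dP| / (P_i + P_{i-1}) per
    frequency row; a silent pair (zero denominator) contributes 0.  With
    ``classical=True`` the per-row sum of |dP| is instead normalised by the
    row's total power over the window (the original soundscape-ecology
    formulation).
    """
    if spec.n_times < 2:
        raise ValueError("window too short: ACI needs at least 2 time columns")
    p = spec.power
    diff = np.abs(np.diff(p, axis=1))
    if classical:
        tot = p.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_row = np.where(tot > 0, diff.sum(axis=1) / tot, 0.0)
        return float(per_row.sum())
    denom = p[:, 1:] + p[:, :-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.sum())


def aci_windows(
    spec: PowerSpectrogram, window_s: float = 600.0, classical: bool = False
) -> tuple[list[AciWindow], float]:
    """Partition a spectrogram into consecutive windows and score each.

    Windows are non-overlapping runs of ``window_s / time_step`` columns;
    a trailing remnant with fewer than 2 columns is dropped.  Returns the
    per-window list and the total (sum over windows), the whole-file
    aggregate.
    """
    if window_s <= 2 * spec.time_step:
        raise ValueError("window_s must exceed two time steps")
    cols_per_win = int(window_s / spec.time_step)
    out: list[AciWindow] = []
    total = 0.0
    idx = 0
    for start_col in range(0, spec.n_times, cols_per_win):
        block = spec.power[:, start_col : start_col + cols_per_win]
        if block.shape[1] < 2:
            break
        sub = PowerSpectrogram(
            power=block,
            freq_edges=spec.freq_edges,
            time_step=spec.time_step,
            start_time=None,
        )
        val = aci_value(sub, classical=classical)
        t0 = None
        if spec.start_time is not None:
            t0 = spec.start_time + timedelta(seconds=start_col * spec.time_step)
        out.append(AciWindow(window_index=idx, start_time=t0, aci=val, n_cols=block.shape[1]))
        total += val
        idx += 1
    return out, total


def hourly_aci(windows: list[AciWindow]) -> list[HourlyAci]:
    """Aggregate window ACI to clock hours (mean of member windows).

    Windows are assigned to the hour of their start time; windows without
    a start time are rejected.
    """
    if not windows:
        return []
    by_hour: dict[int, list[float]] = {}
    order: list[int] = []
    for w in windows:
        if w.start_time is None:
            raise ValueError("hourly aggregation needs windows with start times")
        h = w.start_time.hour
        if h not in by_hour:
            by_hour[h] = []
            order.append(h)
        by_hour[h].append(w.aci)
    return [
        HourlyAci(hour=h, aci=float(np.mean(by_hour[h])), n_windows=len(by_hour[h]))
        for h in order
    ]
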