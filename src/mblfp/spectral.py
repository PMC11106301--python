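"""Per-second spectral statistics for LFP traces.

Pipeline: zero-phase filtering (200 Hz low-pass plus 60/120 Hz notches) →
1-s segmentation → Hamming-windowed Welch PSD per segment on a 1 Hz grid →
per-band average power → high/low power ratio (HLR).

The HLR — average 31–150 Hz ("high") power divided by average 0–12 Hz
("low") power per 1-s segment — is the brain-state statistic everything
downstream consumes.  It is always computed from *unnormalised* band powers;
the robust-scaled spectrogram exists for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import LfpTrace

__all__ = [
    "BandScheme",
    "BandPowerSeries",
    "HlrSeries",
    "preprocess",
    "segment_1s",
    "welch_psd",
    "session_psd",
    "band_powers",
    "band_power_series",
    "band_correlation_matrix",
    "hlr",
    "robust_scale_spectrogram",
    "spectrogram_1s",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 80.0),
    "high_gamma": (81.0, 150.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Named closed frequency intervals in Hz plus the low/high composites.

    Defaults: delta 0–3, theta 4–7, alpha 8–12, beta 13–30, gamma 31–80,
    high-gamma 81–150; composite low = 0–12 (delta+theta+alpha), high =
    31–150 (gamma+high-gamma).  Band membership is closed (lo ≤ f ≤ hi) on
    the PSD frequency grid; the 1-Hz gaps between printed band edges are
    honoured literally.  The 0 Hz bin is excluded from every band
    (``exclude_dc``): DC reflects amplifier offset, not neural activity.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    low: tuple[float, float] = (0.0, 12.0)
    high: tuple[float, float] = (31.0, 150.0)
    exclude_dc: bool = True

    def __post_init__(self) -> None:
        intervals = sorted(self.bands.values())
        for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
            if hi1 >= lo2:
                raise ValueError("named bands must not overlap")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def mask(self, freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
        m = (freqs >= lo) & (freqs <= hi)
        if self.exclude_dc:
            m &= freqs > 0
        return m


@dataclass
class BandPowerSeries:
    """Per-1-s-segment average power per band for one subject.

    ``df`` columns: ``second``, one column per band name, plus composite
    ``low`` and ``high`` columns and a boolean ``valid`` flag.
    """

    subject_id: str
    cohort_id: str
    condition: str
    df: pd.DataFrame
    scheme: BandScheme = field(default_factory=BandScheme)

    def band(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    @property
    def n_segments(self) -> int:
        return len(self.df)


@dataclass
class HlrSeries:
    """Per-segment high-to-low power ratio for one subject.

    Invalid segments (zero or non-finite low-band power) carry NaN values
    and ``valid=False``; they are skipped pairwise in all correlations
    downstream.
    """

    subject_id: str
    cohort_id: str
    condition: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid flags must align")

    def __len__(self) -> int:
        return self.values.size

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cohort_id, self.condition, self.subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "second": np.arange(len(self)),
                "hlr": self.values,
                "valid": self.valid,
            }
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    trace: LfpTrace,
    lowpass_hz: float = 200.0,
    notch_hz: tuple[float, ...] = (60.0, 120.0),
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase low-pass and notch filtering of a raw trace.

    A 4th-order Butterworth low-pass at ``lowpass_hz`` and second-order IIR
    notches at the mains frequency and its harmonic, all applied
    forward-backward (``filtfilt``) so per-second segment boundaries stay
    aligned with the behavioural annotation clock.

    Returns the filtered signal as float64; the integer trace is untouched.
    """
    if trace.fs <= 2 * lowpass_hz:
        raise ValueError(
            f"sampling rate {trace.fs} Hz too low for a {lowpass_hz} Hz low-pass"
        )
    x = trace.astype_float()
    sos = signal.butter(4, lowpass_hz, btype="low", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    for f0 in notch_hz:
        b, a = signal.iirnotch(f0, notch_q, fs=trace.fs)
        x = signal.filtfilt(b, a, x)
    return x


def segment_1s(x: np.ndarray, fs: float) -> np.ndarray:
    """Split a signal into consecutive 1-s blocks; trailing partial second dropped.

    Returns an array of shape ``(n_seconds, fs)``.
    """
    n = int(fs)
    n_seg = len(x) // n
    if n_seg < 1:
        raise ValueError("trace shorter than one second")
    return np.asarray(x[: n_seg * n], dtype=np.float64).reshape(n_seg, n)


# ---------------------------------------------------------------------------
# PSD estimation
# ---------------------------------------------------------------------------

def welch_psd(block: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of 1-s blocks with a Hamming window.

    The window spans the full 1-s block (no sub-window averaging), giving a
    1 Hz frequency grid — any shorter window could not resolve the 0–3 Hz
    delta band.  Accepts a single block of ``fs`` samples or a stack of
    blocks ``(n, fs)``; PSDs are computed along the last axis.

    Returns ``(freqs, psd)`` with density units (power per Hz).
    """
    block = np.asarray(block, dtype=np.float64)
    n = int(fs)
    if block.shape[-1] != n:
        raise ValueError(f"block length {block.shape[-1]} != fs {n}")
    freqs, psd = signal.welch(
        block,
        fs=fs,
        window="hamming",
        nperseg=n,
        noverlap=0,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def session_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of the per-1-s-segment Welch PSDs of a whole trace."""
    blocks = segment_1s(x, fs)
    freqs, psd = welch_psd(blocks, fs)
    return freqs, psd.mean(axis=0)


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, scheme: BandScheme | None = None
) -> dict[str, np.ndarray]:
    """Average PSD density per band (named bands plus low/high composites).

    ``psd`` may be a single PSD or a stack with frequency on the last axis.
    """
    scheme = scheme or BandScheme()
    nyquist = freqs.max()
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in {**scheme.bands, "low": scheme.low, "high": scheme.high}.items():
        if hi > nyquist:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist {nyquist} Hz")
        m = scheme.mask(freqs, lo, hi)
        out[name] = np.asarray(psd)[..., m].mean(axis=-1)
    return out


def band_power_series(
    trace: LfpTrace,
    scheme: BandScheme | None = None,
    *,
    filtered: np.ndarray | None = None,
) -> BandPowerSeries:
    """Full per-second band-power table for one subject's trace.

    If ``filtered`` is given it is used as the (already preprocessed)
    signal; otherwise the raw integer samples are used as-is.
    """
    scheme = scheme or BandScheme()
    x = trace.astype_float() if filtered is None else np.asarray(filtered)
    blocks = segment_1s(x, trace.fs)
    freqs, psd = welch_psd(blocks, trace.fs)
    powers = band_powers(freqs, psd, scheme)
    df = pd.DataFrame({"second": np.arange(blocks.shape[0])})
    for name, vals in powers.items():
        df[name] = vals
    df["valid"] = np.isfinite(psd).all(axis=-1)
    return BandPowerSeries(
        subject_id=trace.subject_id,
        cohort_id=trace.cohort_id,
        condition=trace.condition,
        df=df,
        scheme=scheme,
    )


def band_correlation_matrix(series: list[BandPowerSeries]) -> pd.DataFrame:
    """Average across subjects of per-subject Pearson band-band correlations.

    Constant band series give undefined correlations; those entries are
    excluded from the average (NaN-aware mean).  The result is symmetric
    with a unit diagonal.
    """
    if not series:
        raise ValueError("need at least one band-power series")
    names = series[0].scheme.names
    mats = []
    for s in series:
        sub = s.df.loc[s.df["valid"], names]
        if len(sub) < 2:
            continue
        mats.append(sub.corr(method="pearson").to_numpy())
    if not mats:
        raise ValueError("no series with >=2 valid segments")
    avg = np.nanmean(np.stack(mats), axis=0)
    np.fill_diagonal(avg, 1.0)
    return pd.DataFrame(avg, index=names, columns=names)


# ---------------------------------------------------------------------------
# HLR
# ---------------------------------------------------------------------------

def hlr(series: BandPowerSeries) -> HlrSeries:
    """High-to-low power ratio per segment from unnormalised band powers."""
    low = series.df["low"].to_numpy(dtype=np.float64)
    high = series.df["high"].to_numpy(dtype=np.float64)
    valid = series.df["valid"].to_numpy(dtype=bool) & (low > 0) & np.isfinite(high)
    values = np.full_like(low, np.nan)
    np.divide(high, low, out=values, where=valid)
    return HlrSeries(
        subject_id=series.subject_id,
        cohort_id=series.cohort_id,
        condition=series.condition,
        values=values,
        valid=valid,
    )


def hlr_from_trace(
    trace: LfpTrace,
    scheme: BandScheme | None = None,
    *,
    do_preprocess: bool = True,
) -> HlrSeries:
    """Convenience: preprocess → band powers → HLR in one call."""
    filtered = preprocess(trace) if do_preprocess else None
    return hlr(band_power_series(trace, scheme, filtered=filtered))


# ---------------------------------------------------------------------------
# spectrogram utilities (display/export only)
# ---------------------------------------------------------------------------

def spectrogram_1s(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-second PSD spectrogram: (freqs, seconds, power[freq, time])."""
    blocks = segment_1s(x, fs)
    freqs, psd = welch_psd(blocks, fs)
    return freqs, np.arange(blocks.shape[0], dtype=float), psd.T


def robust_scale_spectrogram(spec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust-scale a spectrogram row-wise: (x − median) / IQR per frequency.

    Returns ``(scaled, row_valid)``; rows with zero IQR cannot be scaled and
    are flagged invalid (NaN).  Display/export only — the HLR is always
    computed from unnormalised powers.
    """
    spec = np.asarray(spec, dtype=np.float64)
    if spec.ndim != 2 or spec.shape[1] < 2:
        raise ValueError("spectrogram must be 2-D with at least 2 time bins")
    med = np.median(spec, axis=1, keepdims=True)
    q75, q25 = np.percentile(spec, [75, 25], axis=1)
    iqr = (q75 - q25)[:, None]
    row_valid = iqr[:, 0] > 0
    scaled = np.full_like(spec, np.nan)
    np.divide(spec - med, iqr, out=scaled, where=row_valid[:, None])
    return scaled, row_valid
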