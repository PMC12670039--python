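"""IRASA decomposition of epoched EEG into aperiodic and oscillatory spectra.

The mixed power spectrum of each trial x channel window is split into an
aperiodic (1/f-like) component, estimated by irregular-resampling
auto-spectral analysis (IRASA), and an oscillatory residual:

* the signal is resampled by each non-integer factor pair ``(h, 1/h)``;
* the spectra of a pair are combined by their geometric mean, which leaves a
  power-law spectrum invariant while displacing oscillatory peaks;
* the median across all ``h`` yields the aperiodic spectrum;
* oscillatory = mixed - aperiodic (no flooring; off-peak values may be
  negative).

Spectra are estimated on a 1 Hz grid from 1 to 35 Hz by a Hann-tapered
periodogram, zero-padded to at least 2 s equivalent so that the grid remains
meaningful for sub-second analysis windows. Five per-trial, per-channel
signals are derived: oscillatory, aperiodic and mixed alpha power (8-13 Hz
band means), and the slope and intercept of a least-squares line fitted to
the aperiodic spectrum in log10-log10 coordinates; aperiodic broadband power
(3-30 Hz) is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import periodogram, resample_poly

from .epochs import EpochSet

#: 1 Hz analysis grid.
DEFAULT_FREQ_GRID = np.arange(1.0, 36.0)
#: Resampling factors 1.10, 1.15, ..., 1.90.
DEFAULT_H_SET = tuple(np.round(np.arange(1.10, 1.901, 0.05), 2))
ALPHA_BAND = (8.0, 13.0)
BROADBAND = (3.0, 30.0)
DEFAULT_FIT_RANGE = (3.0, 30.0)

_MIN_SAMPLES = 64
_MIN_PAD_S = 2.0


def compute_psd(
    series: np.ndarray,
    srate: float,
    freq_grid: np.ndarray = DEFAULT_FREQ_GRID,
) -> np.ndarray:
    """Hann-tapered, zero-padded power spectral density on the 1 Hz grid.

    Operates on the last axis; accepts stacks of series. Power is returned
    in (signal units)^2 / Hz, linearly interpolated onto ``freq_grid``.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    if n < _MIN_SAMPLES:
        raise ValueError(f"series must have >= {_MIN_SAMPLES} samples, got {n}")
    nfft = max(n, int(np.ceil(_MIN_PAD_S * srate)))
    freqs, pxx = periodogram(
        series, fs=srate, window="hann", nfft=nfft, detrend=False, axis=-1
    )
    return _interp_last_axis(freq_grid, freqs, pxx)


def _interp_last_axis(grid, freqs, values):
    """Vectorised linear interpolation of ``values`` (last axis) onto ``grid``."""
    df = freqs[1] - freqs[0]
    pos = (np.asarray(grid) - freqs[0]) / df
    i0 = np.clip(np.floor(pos).astype(int), 0, freqs.size - 2)
    w = pos - i0
    return values[..., i0] * (1.0 - w) + values[..., i0 + 1] * w


def _resample_fraction(h: float) -> tuple[int, int]:
    frac = Fraction(h).limit_denominator(100)
    return frac.numerator, frac.denominator


def irasa_aperiodic(
    series: np.ndarray,
    srate: float,
    h_set=DEFAULT_H_SET,
    freq_grid: np.ndarray = DEFAULT_FREQ_GRID,
) -> np.ndarray:
    """Aperiodic power spectrum by irregular resampling.

    For each factor ``h``: resample the series by ``h`` and ``1/h``
    (polyphase filtering with anti-aliasing, ``h`` approximated by a
    rational fraction with denominator <= 100), compute both spectra on the
    nominal sampling rate — which rescales the frequency axis by ``1/h`` and
    ``h`` respectively — and take the geometric mean of the pair. A
    power-law spectrum is an exact fixed point of this pairing, while
    oscillatory peaks are displaced and suppressed. The median across all
    ``h`` gives the final estimate.
    """
    series = np.asarray(series, dtype=np.float64)
    h_set = tuple(h_set)
    if not h_set or any(h <= 1 for h in h_set):
        raise ValueError("all resampling factors must exceed 1")
    n = series.shape[-1]
    per_h = np.empty(series.shape[:-1] + (len(h_set), len(freq_grid)))
    for j, h in enumerate(h_set):
        p, q = _resample_fraction(h)
        up = resample_poly(series, p, q, axis=-1)
        down = resample_poly(series, q, p, axis=-1)
        if down.shape[-1] < _MIN_SAMPLES:
            raise ValueError(
                f"series too short for factor {h}: downsampled length "
                f"{down.shape[-1]} < {_MIN_SAMPLES} (input length {n})"
            )
        psd_up = compute_psd(up, srate, freq_grid)
        psd_down = compute_psd(down, srate, freq_grid)
        per_h[..., j, :] = np.sqrt(psd_up * psd_down)
    # Small-sample debiasing: single-taper periodogram ordinates are
    # chi^2(2)-distributed, so the geometric mean of an independent pair
    # underestimates sqrt(S1*S2) by a factor Gamma(3/2)^2 = pi/4.
    return (4.0 / np.pi) * np.median(per_h, axis=-2)


@dataclass
class SpectrumSet:
    """Mixed, aperiodic and oscillatory spectra per trial x channel."""

    freqs: np.ndarray
    mixed: np.ndarray
    aperiodic: np.ndarray
    oscillatory: np.ndarray
    h_set: tuple[float, ...]
    labels: np.ndarray
    channels: tuple[str, ...]
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        for arr in (self.mixed, self.aperiodic, self.oscillatory):
            if arr.shape != self.mixed.shape:
                raise ValueError("spectra must share one shape")
        if self.mixed.shape[-1] != self.freqs.size:
            raise ValueError("last axis must match the frequency grid")


def decompose(
    epochs: EpochSet,
    h_set=DEFAULT_H_SET,
    freq_grid: np.ndarray = DEFAULT_FREQ_GRID,
) -> SpectrumSet:
    """Per-trial, per-channel IRASA decomposition of an epoch set."""
    flat = epochs.data.reshape(-1, epochs.n_samples)
    mixed = compute_psd(flat, epochs.srate, freq_grid)
    aperiodic = irasa_aperiodic(flat, epochs.srate, h_set, freq_grid)
    shape = (epochs.n_trials, epochs.n_channels, len(freq_grid))
    mixed = mixed.reshape(shape)
    aperiodic = aperiodic.reshape(shape)
    return SpectrumSet(
        freqs=np.asarray(freq_grid, dtype=float),
        mixed=mixed,
        aperiodic=aperiodic,
        oscillatory=mixed - aperiodic,
        h_set=tuple(h_set),
        labels=epochs.labels.copy(),
        channels=epochs.channels,
        subject_id=epochs.subject_id,
    )


def band_power(
    spectrum: np.ndarray,
    lo: float,
    hi: float,
    freqs: np.ndarray = DEFAULT_FREQ_GRID,
) -> np.ndarray:
    """Mean power over grid frequencies ``lo <= f <= hi`` (inclusive).

    Works on the last axis of a spectrum stack.
    """
    if lo >= hi:
        raise ValueError("band low edge must be below high edge")
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside grid [{freqs[0]}, {freqs[-1]}]")
    mask = (freqs >= lo) & (freqs <= hi)
    return np.asarray(spectrum)[..., mask].mean(axis=-1)


def fit_aperiodic(
    spectrum: np.ndarray,
    fit_lo: float = DEFAULT_FIT_RANGE[0],
    fit_hi: float = DEFAULT_FIT_RANGE[1],
    freqs: np.ndarray = DEFAULT_FREQ_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through the spectrum in log10-log10 coordinates.

    Returns ``(slope, intercept)``: log10-power per log10-Hz and log10 power
    at log10 f = 0. Vectorised over leading axes. Requires strictly positive
    power throughout the fit range.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    mask = (freqs >= fit_lo) & (freqs <= fit_hi)
    if mask.sum() < 2:
        raise ValueError("fit range must contain at least two grid points")
    sub = spectrum[..., mask]
    if np.any(sub <= 0):
        raise ValueError("non-positive power inside the fit range")
    x = np.log10(freqs[mask])
    y = np.log10(sub)
    xc = x - x.mean()
    slope = (y * xc).sum(axis=-1) / (xc**2).sum()
    intercept = y.mean(axis=-1) - slope * x.mean()
    return slope, intercept


#: The five decodable signals plus aperiodic broadband power.
SIGNAL_NAMES = ("osc_alpha", "ap_alpha", "mix_alpha", "slope", "intercept")
ALL_FEATURES = SIGNAL_NAMES + ("ap_broadband",)


@dataclass
class FeatureTable:
    """Per trial x channel signal values with labels carried through."""

    osc_alpha: np.ndarray
    ap_alpha: np.ndarray
    mix_alpha: np.ndarray
    ap_broadband: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    labels: np.ndarray
    channels: tuple[str, ...]
    subject_id: str = "S0"

    def signal(self, name: str) -> np.ndarray:
        """The (trials x channels) matrix of one named signal."""
        if name not in ALL_FEATURES:
            raise KeyError(f"unknown signal {name!r}; choose from {ALL_FEATURES}")
        return getattr(self, name)

    @property
    def n_trials(self) -> int:
        return self.labels.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: subject, trial, channel, label, feature, value."""
        rows = []
        for name in ALL_FEATURES:
            arr = self.signal(name)
            t_idx, c_idx = np.meshgrid(
                np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subject_id,
                        "trial": t_idx.ravel(),
                        "channel": np.asarray(self.channels)[c_idx.ravel()],
                        "label": self.labels[t_idx.ravel()],
                        "feature": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def extract_features(
    spectra: SpectrumSet,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> FeatureTable:
    """Band powers and aperiodic fit parameters from a :class:`SpectrumSet`."""
    freqs = spectra.freqs
    slope, intercept = fit_aperiodic(spectra.aperiodic, *fit_range, freqs=freqs)
    return FeatureTable(
        osc_alpha=band_power(spectra.oscillatory, *ALPHA_BAND, freqs=freqs),
        ap_alpha=band_power(spectra.aperiodic, *ALPHA_BAND, freqs=freqs),
        mix_alpha=band_power(spectra.mixed, *ALPHA_BAND, freqs=freqs),
        ap_broadband=band_power(spectra.aperiodic, *BROADBAND, freqs=freqs),
        slope=slope,
        intercept=intercept,
        labels=spectra.labels.copy(),
        channels=spectra.channels,
        subject_id=spectra.subject_id,
    )
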