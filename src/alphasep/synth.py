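"""Synthetic epoched EEG with known aperiodic and oscillatory ground truth.

Each trial is the sum of

* an aperiodic background whose one-sided power spectral density is
  ``10**offset_log10 * f**(-beta)`` (spectrally shaped white noise),
* an alpha-band sinusoid with a uniformly random phase per trial (induced,
  not evoked, so that ERP subtraction leaves it intact),
* an optional time-locked evoked component identical across trials, and
* additive white measurement noise.

Attention to a cued location modulates the alpha amplitude over posterior
electrodes: the amplitude decreases contralateral and increases ipsilateral
to the attended side. Locations off the horizontal meridian are handled by
cosine tuning: a cue at clock angle theta scales the modulation by
``cos(theta)`` (signed horizontal coordinate), so the 3 and 9 o'clock cues
give the full effect and vertical cues are unlateralised. The aperiodic
background power may be modulated the same way, as a separate knob.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import EpochSet
from .montage import Montage, default_montage


class ConfigError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class GroundTruthConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    n_trials_per_condition
        Trials per cued location.
    n_conditions
        2 (left/right) or 8 (clock positions).
    n_channels
        Must match the montage used for generation.
    srate
        Sampling rate, Hz.
    window_s
        Epoch length in seconds; ``window_s * srate`` must be an integer
        sample count of at least 64.
    beta
        Aperiodic exponent; background PSD is proportional to ``f**(-beta)``.
    offset_log10
        Aperiodic offset: log10 of the background PSD at 1 Hz.
    alpha_freq
        Oscillation frequency in Hz, nominally within the 8-13 Hz alpha band.
    alpha_amp
        Peak amplitude of the alpha sinusoid (signal units).
    osc_mod_depth
        Fractional attentional modulation of the alpha amplitude over
        posterior channels, in [0, 1).
    ap_mod_depth
        Fractional attentional modulation of the aperiodic background power
        over posterior channels, in [0, 1).
    erp_amp
        Amplitude of the common time-locked evoked component (0 disables).
    noise_sd
        Standard deviation of the additive white noise.
    seed
        Seed for all randomness in the generator.
    """

    n_trials_per_condition: int = 40
    n_conditions: int = 8
    n_channels: int = 30
    srate: float = 250.0
    window_s: float = 0.6
    beta: float = 1.5
    offset_log10: float = 1.0
    alpha_freq: float = 10.0
    alpha_amp: float = 2.0
    osc_mod_depth: float = 0.3
    ap_mod_depth: float = 0.1
    erp_amp: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.window_s * self.srate
        if abs(n - round(n)) > 1e-9 or round(n) < 64:
            raise ConfigError(
                "window_s * srate must be an integer sample count >= 64"
            )
        if self.n_conditions not in (2, 8):
            raise ConfigError("n_conditions must be 2 or 8")
        if not (0 <= self.osc_mod_depth < 1 and 0 <= self.ap_mod_depth < 1):
            raise ConfigError("modulation depths must lie in [0, 1)")
        if self.beta < 0:
            raise ConfigError("beta must be non-negative")
        if self.n_trials_per_condition < 1 or self.n_channels < 1:
            raise ConfigError("counts must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.srate))

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * self.n_conditions


def condition_angles_deg(n_conditions: int) -> np.ndarray:
    """Clock angle (degrees, 0 = 3 o'clock, counter-clockwise) per condition.

    With 8 conditions, condition ``k`` sits at clock position
    ``90 - 45 * k`` degrees (k = 0 is 12 o'clock, k = 2 is 3 o'clock,
    k = 6 is 9 o'clock). With 2 conditions, condition 0 is attend-left
    (180 degrees) and condition 1 attend-right (0 degrees).
    """
    if n_conditions == 2:
        return np.array([180.0, 0.0])
    if n_conditions == 8:
        return 90.0 - 45.0 * np.arange(8)
    raise ConfigError("n_conditions must be 2 or 8")


def left_right_labels(n_conditions: int) -> tuple[int, int]:
    """(attend-left, attend-right) condition labels for the MI contrast."""
    if n_conditions == 2:
        return 0, 1
    if n_conditions == 8:
        return 6, 2  # 9 o'clock, 3 o'clock
    raise ConfigError("n_conditions must be 2 or 8")


def _shaped_background(
    beta: float,
    offset_log10: float,
    n_samples: int,
    srate: float,
    rng: np.random.Generator,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Gaussian series with one-sided PSD ``10**offset_log10 * f**(-beta)``.

    Fourier synthesis: complex Gaussian amplitudes scaled so the expected
    periodogram equals the target density; DC fixed to zero.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    psd = np.zeros_like(freqs)
    psd[1:] = 10.0**offset_log10 * freqs[1:] ** (-beta)
    # E|X_k|^2 = S(f_k) * srate * n / 2 makes the one-sided periodogram unbiased
    scale = np.sqrt(psd * srate * n_samples / 2.0)
    full = shape + (freqs.size,)
    z = (rng.standard_normal(full) + 1j * rng.standard_normal(full)) / np.sqrt(2.0)
    return np.fft.irfft(z * scale, n=n_samples, axis=-1)


def generate_aperiodic_background(
    beta: float,
    offset_log10: float,
    n_samples: int,
    srate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One realisation of the aperiodic (1/f-like) background.

    Returns a real series of length ``n_samples`` whose expected power
    spectral density is ``10**offset_log10 * f**(-beta)``.
    """
    if n_samples < 64:
        raise ConfigError("n_samples must be >= 64")
    if beta < 0:
        raise ConfigError("beta must be non-negative")
    return _shaped_background(beta, offset_log10, int(n_samples), srate, rng)


def _erp_waveform(times: np.ndarray, amp: float) -> np.ndarray:
    """Time-locked evoked component: a Gaussian-windowed 5 Hz wavelet."""
    t0, width = 0.15, 0.05
    return amp * np.exp(-((times - t0) ** 2) / (2 * width**2)) * np.sin(
        2 * np.pi * 5.0 * (times - t0)
    )


def _hemisphere_signs(montage: Montage) -> np.ndarray:
    """Per-channel modulation sign: -1 left posterior, +1 right posterior, 0 else."""
    signs = np.zeros(montage.n_channels)
    signs[montage.indices(montage.left_posterior)] = -1.0
    signs[montage.indices(montage.right_posterior)] = +1.0
    return signs


def generate_attention_epochs(
    config: GroundTruthConfig, montage: Montage | None = None
) -> EpochSet:
    """Synthesise epochs with attentional modulation of posterior alpha.

    For a posterior channel with hemisphere sign ``h`` (-1 left, +1 right)
    and a cue with horizontal coordinate ``c = cos(theta)`` (+1 = right),
    the alpha amplitude is ``alpha_amp * (1 + osc_mod_depth * h * c)`` and
    the background power is scaled by ``1 + ap_mod_depth * h * c``: the
    signal decreases contralateral and increases ipsilateral to the cue.
    """
    montage = montage if montage is not None else default_montage()
    if montage.n_channels != config.n_channels:
        raise ConfigError(
            f"montage has {montage.n_channels} channels, "
            f"config expects {config.n_channels}"
        )
    rng = np.random.default_rng(config.seed)
    n_trials, n_ch, n_samp = config.n_trials, config.n_channels, config.n_samples

    labels = np.repeat(np.arange(config.n_conditions), config.n_trials_per_condition)
    labels = rng.permutation(labels)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_trials)
    background = _shaped_background(
        config.beta, config.offset_log10, n_samp, config.srate, rng,
        shape=(n_trials, n_ch),
    )
    noise = config.noise_sd * rng.standard_normal((n_trials, n_ch, n_samp))

    hsign = _hemisphere_signs(montage)  # (n_ch,)
    horiz = np.cos(np.deg2rad(condition_angles_deg(config.n_conditions)))
    horiz[np.abs(horiz) < 1e-12] = 0.0
    cue = horiz[labels]  # (n_trials,)

    mod = hsign[None, :] * cue[:, None]  # (n_trials, n_ch)
    alpha_amp = config.alpha_amp * (1.0 + config.osc_mod_depth * mod)
    ap_scale = np.sqrt(1.0 + config.ap_mod_depth * mod)

    times = np.arange(n_samp) / config.srate
    alpha = np.sin(
        2 * np.pi * config.alpha_freq * times[None, :] + phases[:, None]
    )  # (n_trials, n_samp)

    data = (
        ap_scale[:, :, None] * background
        + alpha_amp[:, :, None] * alpha[:, None, :]
        + noise
    )
    if config.erp_amp != 0.0:
        data += _erp_waveform(times, config.erp_amp)[None, None, :]

    return EpochSet(
        data=data,
        srate=config.srate,
        labels=labels,
        channels=montage.channel_names,
        subject_id=f"synth-{config.seed}",
    )


def generate_null_epochs(
    config: GroundTruthConfig,
    montage: Montage | None = None,
    balanced: bool = True,
) -> EpochSet:
    """Epochs with zero attentional modulation and random labels.

    Both modulation depths are forced to 0, making the trial distribution
    identical across conditions; labels are therefore pure noise. With
    ``balanced=True`` each condition receives exactly
    ``n_trials_per_condition`` trials (in random order); otherwise labels
    are drawn i.i.d. uniform.
    """
    null_cfg = replace(config, osc_mod_depth=0.0, ap_mod_depth=0.0)
    epochs = generate_attention_epochs(null_cfg, montage)
    if not balanced:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        epochs.labels = rng.integers(0, config.n_conditions, size=config.n_trials)
    return epochs
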