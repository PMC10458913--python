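"""Beat denoising: interpolation, baseline removal, notch, wavelet, z-norm.

The per-beat pipeline runs five stages in a fixed order, each individually
toggleable:

1. contact-loss interpolation — NaN-sentinel gaps filled by linear or
   cubic interpolation, with constant extension at the edges;
2. baseline-drift removal — two-pass running-median baseline estimate
   (short window to reject QRS spikes, long window to track the wander),
   Gaussian-smoothed to suppress beat leakage, subtracted from the beat;
3. powerline notch — second-order IIR notch applied forward-backward
   (zero phase), default 50 Hz, quality 30;
4. wavelet denoising — discrete wavelet decomposition (Daubechies-4,
   4 levels by default) with universal-threshold shrinkage of the detail
   coefficients, sigma estimated from the finest details by the
   median-absolute-deviation rule;
5. per-beat z-normalization to zero mean and unit population standard
   deviation (constant beats map to all-zeros).

Every stage preserves beat length and acts on rows independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import interpolate as _interp
from scipy import ndimage, signal


class UnrecoverableBeatError(ValueError):
    """Raised when a beat has no observed samples to interpolate from."""


class DenoiseConfigError(ValueError):
    """Raised for invalid denoiser settings (windows, levels, frequencies)."""


@dataclass(frozen=True)
class DenoiseConfig:
    """Tunables of the five-stage denoiser.

    Windows are in seconds; ``notch_freq`` in Hz and must stay below the
    Nyquist frequency; ``decomposition_levels`` must satisfy
    ``2**levels <= beat_length``.
    """

    interpolation_kind: str = "linear"  # {"linear", "cubic"}
    baseline_window_short: float = 0.25
    baseline_window_long: float = 0.96
    baseline_smooth: float = 0.08
    notch_freq: float = 50.0
    notch_quality: float = 30.0
    wavelet_family: str = "db4"
    decomposition_levels: int = 4
    threshold_rule: str = "universal-soft"  # {"universal-soft", "universal-hard"}
    enable_interpolation: bool = True
    enable_baseline: bool = True
    enable_notch: bool = True
    enable_wavelet: bool = True
    znormalize: bool = True

    def validate(self, sampling_rate: float, beat_length: int) -> None:
        if self.interpolation_kind not in ("linear", "cubic"):
            raise DenoiseConfigError(
                f"interpolation_kind must be 'linear' or 'cubic', "
                f"got {self.interpolation_kind!r}"
            )
        if self.baseline_window_short <= 0 or self.baseline_window_long <= 0:
            raise DenoiseConfigError("baseline windows must be > 0 seconds")
        if self.baseline_smooth < 0:
            raise DenoiseConfigError("baseline_smooth must be >= 0 seconds")
        if self.notch_freq >= sampling_rate / 2:
            raise DenoiseConfigError(
                f"notch_freq={self.notch_freq} Hz must be below the Nyquist "
                f"frequency {sampling_rate / 2} Hz"
            )
        if self.threshold_rule not in ("universal-soft", "universal-hard"):
            raise DenoiseConfigError(
                f"unknown threshold_rule {self.threshold_rule!r}"
            )
        if not (1 <= self.decomposition_levels
                and 2 ** self.decomposition_levels <= beat_length):
            raise DenoiseConfigError(
                f"decomposition_levels={self.decomposition_levels} too deep "
                f"for beat_length={beat_length}"
            )

    def disabled(self) -> "DenoiseConfig":
        """Copy of this config with every stage switched off."""
        return replace(
            self,
            enable_interpolation=False,
            enable_baseline=False,
            enable_notch=False,
            enable_wavelet=False,
            znormalize=False,
        )


def interpolate_missing(
    beat: np.ndarray,
    mask: np.ndarray | None = None,
    kind: str = "linear",
) -> np.ndarray:
    """Fill contact-loss gaps by interpolation over the observed samples.

    ``mask`` flags the missing positions; when None it is derived from NaN
    sentinels.  Edge gaps are filled with the nearest observed value.
    """
    beat = np.asarray(beat, dtype=float)
    if mask is None:
        mask = ~np.isfinite(beat)
    else:
        mask = np.asarray(mask, dtype=bool) | ~np.isfinite(beat)
    if not mask.any():
        return beat.copy()
    if mask.all():
        raise UnrecoverableBeatError("beat has no observed samples")
    idx = np.arange(beat.size)
    obs = ~mask
    out = beat.copy()
    if kind == "linear" or obs.sum() < 4:
        # np.interp extends with the boundary values, the stated edge rule
        out[mask] = np.interp(idx[mask], idx[obs], beat[obs])
    elif kind == "cubic":
        spline = _interp.CubicSpline(idx[obs], beat[obs])
        inner = mask & (idx >= idx[obs][0]) & (idx <= idx[obs][-1])
        out[inner] = spline(idx[inner])
        out[mask & (idx < idx[obs][0])] = beat[obs][0]
        out[mask & (idx > idx[obs][-1])] = beat[obs][-1]
    else:
        raise DenoiseConfigError(f"unknown interpolation kind {kind!r}")
    return out


def _odd_window(seconds: float, sampling_rate: float, n: int) -> int:
    w = int(round(seconds * sampling_rate))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    if w > n:
        raise DenoiseConfigError(
            f"median window of {w} samples exceeds beat length {n}"
        )
    return w


def remove_baseline_drift(
    beat: np.ndarray,
    sampling_rate: float = 125.0,
    window_short: float = 0.25,
    window_long: float = 0.96,
    smooth: float = 0.08,
) -> np.ndarray:
    """Subtract a smoothed two-pass running-median baseline estimate.

    The short window suppresses QRS spikes in the estimate, the long
    window tracks the slow wander, and a final Gaussian smoothing pass
    (``smooth`` seconds of standard deviation) suppresses residual beat
    leakage so wide ventricular complexes are not absorbed into the
    baseline.  Returns beat - baseline.
    """
    beat = np.asarray(beat, dtype=float)
    n = beat.size
    ws = _odd_window(window_short, sampling_rate, n)
    wl = _odd_window(window_long, sampling_rate, n)
    baseline = ndimage.median_filter(beat, size=ws, mode="nearest")
    baseline = ndimage.median_filter(baseline, size=wl, mode="nearest")
    if smooth > 0:
        baseline = ndimage.gaussian_filter1d(
            baseline, sigma=smooth * sampling_rate, mode="nearest"
        )
    return beat - baseline


def notch_filter(
    beat: np.ndarray,
    sampling_rate: float = 125.0,
    notch_freq: float = 50.0,
    quality: float = 30.0,
) -> np.ndarray:
    """Zero-phase second-order IIR notch at the powerline frequency."""
    beat = np.asarray(beat, dtype=float)
    if not np.all(np.isfinite(beat)):
        raise ValueError("notch_filter requires a finite input beat")
    if notch_freq >= sampling_rate / 2:
        raise DenoiseConfigError(
            f"notch_freq={notch_freq} Hz must be below Nyquist "
            f"{sampling_rate / 2} Hz"
        )
    b, a = signal.iirnotch(notch_freq, quality, fs=sampling_rate)
    return signal.filtfilt(b, a, beat)


def wavelet_denoise(
    beat: np.ndarray,
    family: str = "db4",
    levels: int = 4,
    threshold_rule: str = "universal-soft",
    threshold: float | None = None,
) -> np.ndarray:
    """Universal-threshold wavelet shrinkage of the detail coefficients.

    The threshold defaults to ``sigma * sqrt(2 ln N)`` with sigma estimated
    as ``median(|finest details|) / 0.6745``; pass ``threshold`` to
    override (0 reproduces the input up to numerical error).
    """
    beat = np.asarray(beat, dtype=float)
    n = beat.size
    wavelet = pywt.Wavelet(family)
    if levels < 1 or 2 ** levels > n:
        raise DenoiseConfigError(
            f"levels={levels} not decomposable for beat length {n}"
        )
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    if levels > max_level:
        raise DenoiseConfigError(
            f"levels={levels} exceeds max decomposable depth {max_level} "
            f"for {family} at beat length {n}"
        )
    coeffs = pywt.wavedec(beat, wavelet, level=levels, mode="periodization")
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(n))
    if threshold_rule not in ("universal-soft", "universal-hard"):
        raise DenoiseConfigError(f"unknown threshold_rule {threshold_rule!r}")
    mode = "soft" if threshold_rule == "universal-soft" else "hard"
    if threshold <= 0:  # nothing to shrink
        shrunk = coeffs
    else:
        shrunk = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode=mode) for c in coeffs[1:]
        ]
    return pywt.waverec(shrunk, wavelet, mode="periodization")[:n]


def znormalize_beat(beat: np.ndarray) -> np.ndarray:
    """Standardize a beat to mean 0, population std 1 (constant -> zeros)."""
    beat = np.asarray(beat, dtype=float)
    mu = beat.mean()
    sigma = beat.std()
    if sigma < 1e-12:
        return np.zeros_like(beat)
    return (beat - mu) / sigma


def denoise_beats(
    beats: np.ndarray,
    masks: np.ndarray | None = None,
    config: DenoiseConfig | None = None,
    sampling_rate: float = 125.0,
) -> np.ndarray:
    """Run the staged denoiser over every row of a beat matrix.

    Stage order is fixed: interpolate -> baseline -> notch -> wavelet ->
    z-normalize, with each stage honoring its enable flag.  Errors are
    re-raised with the offending beat index attached.
    """
    beats = np.asarray(beats, dtype=float)
    if config is None:
        config = DenoiseConfig()
    config.validate(sampling_rate, beats.shape[1])
    out = np.empty_like(beats)
    for i in range(beats.shape[0]):
        row = beats[i]
        mask = masks[i] if masks is not None else None
        try:
            if config.enable_interpolation:
                row = interpolate_missing(row, mask, config.interpolation_kind)
            if config.enable_baseline:
                row = remove_baseline_drift(
                    row,
                    sampling_rate,
                    config.baseline_window_short,
                    config.baseline_window_long,
                    config.baseline_smooth,
                )
            if config.enable_notch:
                row = notch_filter(
                    row, sampling_rate, config.notch_freq, config.notch_quality
                )
            if config.enable_wavelet:
                row = wavelet_denoise(
                    row,
                    config.wavelet_family,
                    config.decomposition_levels,
                    config.threshold_rule,
                )
            if config.znormalize:
                row = znormalize_beat(row)
        except Exception as exc:
            raise type(exc)(f"beat {i}: {exc}") from exc
        out[i] = row
    return out
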