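"""Synthetic five-class heartbeat generator with an ECG noise taxonomy.

Beat morphology is modelled as a sum of Gaussian bumps standing in for the
P wave, the QRS complex (Q, R, S deflections) and the T wave.  Each of the
five beat classes distorts the template in the way its arrhythmia distorts
a real beat:

* N — normal morphology (P, QRS, T at textbook positions).
* S — supraventricular premature: early, attenuated P wave and an
  advanced (early) QRS/T.
* V — premature ventricular contraction: widened, high-amplitude QRS,
  absent P, discordant (inverted) T.
* F — fusion of ventricular and normal: pointwise mixture of the N and V
  morphologies.
* Q — unclassifiable: irregular multi-bump shape with low correlation to
  the other classes.

Noise components mirror the artefacts seen in ambulatory recordings:
additive Gaussian noise, sinusoidal baseline drift, sinusoidal powerline
interference, random-walk motion bursts, and contact-loss gaps encoded as
NaN sentinels plus a boolean mask (arrays stay rectangular).

All operations are pure functions of their arguments and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Missing-value sentinel used for contact-loss samples.
MISSING = np.nan

N_CLASSES = 5

# Gaussian-bump constants per class: (center, width, amplitude), all centers
# and widths as fractions of the beat duration.  See docs/methods.md for the
# rationale behind each entry.
_BUMPS: dict[int, tuple[tuple[float, float, float], ...]] = {
    # N: P, Q, R, S, T
    0: (
        (0.18, 0.025, 0.15),
        (0.355, 0.012, -0.12),
        (0.40, 0.016, 1.00),
        (0.445, 0.012, -0.22),
        (0.62, 0.050, 0.30),
    ),
    # S: early reduced P, advanced QRS/T
    1: (
        (0.09, 0.020, 0.06),
        (0.305, 0.012, -0.12),
        (0.35, 0.016, 0.95),
        (0.395, 0.012, -0.22),
        (0.56, 0.045, 0.25),
    ),
    # V: no P, wide high-amplitude QRS (~2x normal width), discordant T
    2: (
        (0.38, 0.030, 1.25),
        (0.47, 0.028, -0.45),
        (0.66, 0.055, -0.35),
    ),
    # Q: irregular low-correlation shape
    4: (
        (0.15, 0.045, 0.35),
        (0.35, 0.050, -0.40),
        (0.55, 0.030, 0.50),
        (0.80, 0.040, -0.30),
    ),
}

FUSION_CLASS = 3
DEFAULT_FUSION_WEIGHT = 0.5

# Per-beat morphological jitter (dimensionless): std of bump-center shift,
# multiplicative width/amplitude spread, and global amplitude spread.
_JITTER_CENTER = 0.004
_JITTER_WIDTH = 0.05
_JITTER_AMP = 0.05
_JITTER_GLOBAL = 0.05


class InvalidClassError(ValueError):
    """Raised for a beat class id outside 0..4."""


class InvalidNoiseSpecError(ValueError):
    """Raised when a NoiseSpec violates its invariants."""


class EmptyDatasetError(ValueError):
    """Raised when a dataset request contains no beats."""


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the additive-noise and contact-loss processes.

    Amplitudes are in the same (z-score-like) units as the clean beats;
    frequencies in Hz; ``motion_burst_rate`` is the expected number of
    motion-artefact bursts per beat; ``contact_loss_prob`` is the
    probability that a beat contains one contact-loss gap of
    ``gap_length`` samples.
    """

    gaussian_sigma: float = 0.0
    baseline_amplitude: float = 0.0
    baseline_freq: float = 0.3
    powerline_amplitude: float = 0.0
    powerline_freq: float = 50.0
    motion_burst_rate: float = 0.0
    motion_amplitude: float = 0.0
    contact_loss_prob: float = 0.0
    gap_length: int = 10

    def validate(self, sampling_rate: float) -> None:
        """Check invariants; raise :class:`InvalidNoiseSpecError` on violation."""
        nonneg = {
            "gaussian_sigma": self.gaussian_sigma,
            "baseline_amplitude": self.baseline_amplitude,
            "powerline_amplitude": self.powerline_amplitude,
            "motion_burst_rate": self.motion_burst_rate,
            "motion_amplitude": self.motion_amplitude,
            "contact_loss_prob": self.contact_loss_prob,
            "gap_length": self.gap_length,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise InvalidNoiseSpecError(f"{name} must be >= 0, got {value}")
        if self.contact_loss_prob > 1:
            raise InvalidNoiseSpecError(
                f"contact_loss_prob must be <= 1, got {self.contact_loss_prob}"
            )
        nyquist = sampling_rate / 2.0
        for name, freq in (
            ("baseline_freq", self.baseline_freq),
            ("powerline_freq", self.powerline_freq),
        ):
            if freq >= nyquist:
                raise InvalidNoiseSpecError(
                    f"{name}={freq} Hz is not below the Nyquist frequency "
                    f"{nyquist} Hz"
                )

    @property
    def is_silent(self) -> bool:
        """True when every noise component is switched off."""
        return (
            self.gaussian_sigma == 0
            and self.baseline_amplitude == 0
            and self.powerline_amplitude == 0
            and (self.motion_burst_rate == 0 or self.motion_amplitude == 0)
            and self.contact_loss_prob == 0
        )


def _bump_sum(t: np.ndarray, bumps, rng: np.random.Generator | None) -> np.ndarray:
    """Sum of Gaussian bumps at normalized times ``t``, optionally jittered."""
    beat = np.zeros_like(t)
    if rng is None:
        g = 1.0
    else:
        g = 1.0 + _JITTER_GLOBAL * rng.standard_normal()
    for center, width, amp in bumps:
        if rng is not None:
            center = center + _JITTER_CENTER * rng.standard_normal()
            width = width * (1.0 + _JITTER_WIDTH * rng.standard_normal())
            amp = amp * (1.0 + _JITTER_AMP * rng.standard_normal())
        width = max(width, 1e-4)
        beat += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return g * beat


def class_template(class_id: int, beat_length: int = 187) -> np.ndarray:
    """Noise-free, jitter-free reference waveform for a beat class.

    The F template is the pointwise mean of the N and V templates.
    """
    _check_class(class_id)
    t = np.linspace(0.0, 1.0, beat_length)
    if class_id == FUSION_CLASS:
        return 0.5 * (_bump_sum(t, _BUMPS[0], None) + _bump_sum(t, _BUMPS[2], None))
    return _bump_sum(t, _BUMPS[class_id], None)


def generate_beat(
    class_id: int,
    beat_length: int = 187,
    seed: int = 0,
    fusion_weight: float = DEFAULT_FUSION_WEIGHT,
) -> np.ndarray:
    """Generate one clean heartbeat with seeded morphological jitter.

    Parameters
    ----------
    class_id : int
        Beat class, 0=N, 1=S, 2=V, 3=F, 4=Q.
    beat_length : int
        Number of samples (>= 32).
    seed : int
        Seed for the per-beat jitter; identical seeds give bitwise
        identical beats.
    fusion_weight : float
        Mixing weight of the V morphology in the fusion class; the F beat
        is ``(1 - w) * N + w * V`` generated at the same seed.
    """
    _check_class(class_id)
    if beat_length < 32:
        raise ValueError(f"beat_length must be >= 32, got {beat_length}")
    if class_id == FUSION_CLASS:
        n_beat = generate_beat(0, beat_length, seed)
        v_beat = generate_beat(2, beat_length, seed)
        return (1.0 - fusion_weight) * n_beat + fusion_weight * v_beat
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, beat_length)
    return _bump_sum(t, _BUMPS[class_id], rng)


def apply_noise(
    beat: np.ndarray,
    spec: NoiseSpec,
    sampling_rate: float = 125.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add the noise processes of ``spec`` to a beat.

    Returns the noisy beat and a contact-loss mask (True where the
    electrode signal was lost; those samples are set to the NaN sentinel).
    Components are drawn in a fixed order so output is deterministic under
    the seed.  An all-zero spec returns the input unchanged.
    """
    spec.validate(sampling_rate)
    beat = np.asarray(beat, dtype=float)
    n = beat.shape[-1]
    mask = np.zeros(n, dtype=bool)
    if spec.is_silent:
        return beat.copy(), mask

    rng = np.random.default_rng(seed)
    out = beat.copy()
    t = np.arange(n) / sampling_rate

    if spec.gaussian_sigma > 0:
        out += rng.normal(0.0, spec.gaussian_sigma, n)
    if spec.baseline_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += spec.baseline_amplitude * np.sin(
            2.0 * np.pi * spec.baseline_freq * t + phase
        )
    if spec.powerline_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        out += spec.powerline_amplitude * np.sin(
            2.0 * np.pi * spec.powerline_freq * t + phase
        )
    if spec.motion_burst_rate > 0 and spec.motion_amplitude > 0:
        n_bursts = rng.poisson(spec.motion_burst_rate)
        for _ in range(n_bursts):
            # slow electrode-movement excursion: a Brownian bridge (random
            # walk pinned to zero at both ends) spanning 50-90% of the beat
            burst_len = int(rng.integers(n // 2, max(n // 2 + 1, (9 * n) // 10)))
            start = int(rng.integers(0, max(1, n - burst_len + 1)))
            walk = np.cumsum(rng.standard_normal(burst_len))
            walk -= np.linspace(walk[0], walk[-1], burst_len)
            scale = np.abs(walk).max()
            if scale > 0:
                walk = walk / scale * spec.motion_amplitude
            out[start : start + burst_len] += walk
    if spec.contact_loss_prob > 0 and rng.random() < spec.contact_loss_prob:
        gap = min(int(spec.gap_length), n)
        if gap > 0:
            start = int(rng.integers(0, n - gap + 1))
            mask[start : start + gap] = True
            out[mask] = MISSING
    return out, mask


def generate_dataset(
    class_counts: dict[int, int],
    beat_length: int = 187,
    spec: NoiseSpec | None = None,
    seed: int = 0,
    sampling_rate: float = 125.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a shuffled labelled beat dataset.

    Parameters
    ----------
    class_counts : dict
        Mapping class id -> number of beats (counts >= 0).
    spec : NoiseSpec, optional
        Noise processes applied per beat; None means clean beats.

    Returns
    -------
    beats : (n, beat_length) float array (NaN where contact was lost)
    labels : (n,) int array
    masks : (n, beat_length) bool array of contact-loss flags
    """
    if spec is None:
        spec = NoiseSpec()
    spec.validate(sampling_rate)
    for class_id, count in class_counts.items():
        _check_class(class_id)
        if count < 0:
            raise ValueError(f"count for class {class_id} must be >= 0")
    total = sum(class_counts.values())
    if total == 0:
        raise EmptyDatasetError("class_counts request zero beats")

    ss = np.random.SeedSequence(seed)
    beat_seeds = ss.generate_state(2 * total, dtype=np.uint32)
    beats = np.empty((total, beat_length), dtype=float)
    labels = np.empty(total, dtype=int)
    masks = np.zeros((total, beat_length), dtype=bool)
    row = 0
    for class_id in sorted(class_counts):
        for _ in range(class_counts[class_id]):
            clean = generate_beat(class_id, beat_length, int(beat_seeds[2 * row]))
            noisy, mask = apply_noise(
                clean, spec, sampling_rate, int(beat_seeds[2 * row + 1])
            )
            beats[row] = noisy
            masks[row] = mask
            labels[row] = class_id
            row += 1
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(total)
    return beats[order], labels[order], masks[order]


def _check_class(class_id: int) -> None:
    if not (isinstance(class_id, (int, np.integer)) and 0 <= class_id < N_CLASSES):
        raise InvalidClassError(
            f"class_id must be an integer in 0..{N_CLASSES - 1}, got {class_id!r}"
        )
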