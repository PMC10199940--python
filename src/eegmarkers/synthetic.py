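"""Synthetic EEG cohorts with the spectral signature of Alzheimer's disease.

The generator emulates the qualitative structure the analysis relies on:
AD signals show a shift of spectral weight from the faster rhythms
(alpha, beta) into the slow ones (delta, theta), a slowing of activity
*within* the delta band, and extra temporal smoothing that lowers every
complexity measure. Healthy eyes-closed recordings carry more alpha
power than eyes-open ones. Channels are statistically independent --
no volume conduction or artifacts are modelled.

Each channel is a Gaussian process synthesised in the frequency domain:
a 1/f background plus flat narrowband components for the four rhythms,
band-limited to 0.5-30 Hz and renormalised to unit variance. With
``delta_shift = 0`` and ``autocorr_boost = 0`` the AD and healthy
generators are statistically identical, which provides an exact null
for calibration tests.

All randomness flows from a single integer seed through a counter-based
derivation per (group, subject, channel), so any record can be
regenerated in isolation and generation order is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CHANNELS_10_20, GROUPS, EEGRecord, validate_group

__all__ = ["CohortSpec", "effect_spec", "generate_subject", "generate_cohort",
           "white_noise"]

# Baseline band energies (arbitrary units; only ratios matter after the
# per-channel unit-variance renormalisation).
_BASE_ENERGY = {"delta": 1.0, "theta": 0.7, "alpha": 1.2, "beta": 0.6}
_ALPHA_CLOSED = 2.2          # alpha energy replacing 1.2 when eyes are closed
_PINK_ENERGY = 1.0           # 1/f background energy
_SUBJECT_SIGMA = 0.25        # log-normal between-subject spread of band energies
_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 15.0), "beta": (15.0, 30.0)}
_DELTA_LOW = 0.5
_DELTA_HIGH = 4.0
_DELTA_SLOWING = 3.0         # Hz removed from the delta upper edge at delta_shift=1
_BAND_LIMIT = (0.5, 30.0)

_GROUP_CODE = {"A": 1, "B": 2, "C": 3, "D": 4}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_healthy, n_ad : int
        Subjects per eye condition in the healthy (A, B) and AD (C, D)
        groups. Defaults mirror a 12-control / 80-patient study arm.
    fs : float
        Sampling rate in Hz; ``fs * duration`` must be an integer.
    duration : float
        Segment length in seconds.
    n_channels : int
        Number of electrodes, taken in order from the 10-20 list.
    delta_shift : float
        Effect size >= 0 scaling the AD spectral slowing: relative
        weight moves from alpha/beta into delta/theta (delta and theta
        energies amplified, alpha and beta attenuated) and the delta
        band's own upper edge is lowered proportionally. 0 disables
        the effect.
    autocorr_boost : float
        Effect size >= 0: standard deviation, in samples, of a Gaussian
        smoothing kernel applied to AD signals only. 0 disables it.
        The default keeps the two AD effects in the ratio 1:4 used
        throughout the package's effect-size grids.
    seed : int
        Root seed for the whole cohort.
    """

    n_healthy: int = 12
    n_ad: int = 80
    fs: float = 128.0
    duration: float = 8.0
    n_channels: int = 19
    delta_shift: float = 0.5
    autocorr_boost: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        if not 1 <= self.n_channels <= len(CHANNELS_10_20):
            raise ValueError(f"n_channels must be in [1, {len(CHANNELS_10_20)}]")
        if self.delta_shift < 0 or self.autocorr_boost < 0:
            raise ValueError("effect sizes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return CHANNELS_10_20[: self.n_channels]


def _band_energies(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict[str, float]:
    """Target energy per spectral component for one subject."""
    e = dict(_BASE_ENERGY)
    if group in ("B", "D"):
        e["alpha"] = _ALPHA_CLOSED
    if group in ("C", "D") and spec.delta_shift > 0:
        # spectral slowing: weight moves out of the fast rhythms into the
        # slow ones (channels are renormalised to unit variance, so only
        # the relative profile matters)
        s = spec.delta_shift
        e["delta"] *= 1.0 + 0.8 * s
        e["theta"] *= 1.0 + 0.5 * s
        e["alpha"] *= 1.0 - 0.4 * s
        e["beta"] *= 1.0 - 0.4 * s
    e["pink"] = _PINK_ENERGY
    # Between-subject variability: independent log-normal factor per band.
    for k in e:
        e[k] *= float(np.exp(_SUBJECT_SIGMA * rng.standard_normal()))
    return e


def _variance_profile(spec: CohortSpec, group: str, energies: dict[str, float],
                      freqs: np.ndarray) -> np.ndarray:
    """Per-frequency-bin variance implied by the band energies."""
    profile = np.zeros_like(freqs)
    edges = dict(_BAND_EDGES)
    hi = _DELTA_HIGH
    if group in ("C", "D"):
        hi -= _DELTA_SLOWING * spec.delta_shift  # in-band slowing of delta
    edges["delta"] = (_DELTA_LOW, max(hi, _DELTA_LOW + 0.5))
    for band, (f1, f2) in edges.items():
        mask = (freqs >= f1) & (freqs < f2)
        if mask.any():
            profile[mask] += energies[band] / mask.sum()
    pink_mask = (freqs >= _BAND_LIMIT[0]) & (freqs <= _BAND_LIMIT[1])
    pink = np.zeros_like(freqs)
    pink[pink_mask] = 1.0 / np.maximum(freqs[pink_mask], _BAND_LIMIT[0])
    if pink.sum() > 0:
        profile += energies["pink"] * pink / pink.sum()
    return profile


def _subject_rng(spec: CohortSpec, group: str, subject_index: int,
                 stream: int) -> np.random.Generator:
    key = (_GROUP_CODE[group], subject_index, stream)
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> EEGRecord:
    """Generate one subject's record, reproducible from (seed, group, index)."""
    validate_group(group)
    T = spec.n_samples
    freqs = np.fft.rfftfreq(T, d=1.0 / spec.fs)
    weights_rng = _subject_rng(spec, group, subject_index, 0)
    energies = _band_energies(spec, group, weights_rng)
    profile = _variance_profile(spec, group, energies, freqs)
    amplitude = np.sqrt(profile)
    if group in ("C", "D") and spec.autocorr_boost > 0:
        # Gaussian smoothing kernel of std `autocorr_boost` samples,
        # applied as its (real) transfer function.
        sigma_t = spec.autocorr_boost / spec.fs
        amplitude = amplitude * np.exp(-2.0 * (np.pi * freqs * sigma_t) ** 2)
    signal = np.empty((spec.n_channels, T))
    for ch in range(spec.n_channels):
        rng = _subject_rng(spec, group, subject_index, ch + 1)
        z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        x = np.fft.irfft(amplitude * z, n=T)
        sd = x.std()
        if sd == 0:  # pragma: no cover - cannot happen with a nonzero profile
            raise RuntimeError("degenerate synthetic channel")
        signal[ch] = x / sd
    return EEGRecord(
        subject_id=f"{group}{subject_index:03d}",
        group=group,
        channel_names=spec.channel_names,
        signal=signal,
        fs=spec.fs,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecord]:
    """Generate the full four-group cohort (A, B healthy; C, D probable AD)."""
    if spec.n_healthy < 1 or spec.n_ad < 1:
        raise ValueError("group sizes must be >= 1")
    records: list[EEGRecord] = []
    for group in GROUPS:
        n = spec.n_healthy if group in ("A", "B") else spec.n_ad
        for i in range(n):
            records.append(generate_subject(spec, group, i))
    return records


def effect_spec(effect: float, **overrides) -> CohortSpec:
    """Cohort spec with the AD phenotype scaled by one effect level.

    ``effect`` sets ``delta_shift`` directly and ``autocorr_boost`` to
    0.25x that value, the fixed ratio of the two AD effects used in the
    package's effect-size grids; ``effect = 0`` is the exact null.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    return CohortSpec(delta_shift=effect, autocorr_boost=0.25 * effect,
                      **overrides)


def white_noise(T: int, seed: int) -> np.ndarray:
    """I.i.d. standard-normal series of length ``T`` (benchmark input)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return np.random.default_rng(seed).standard_normal(T)
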