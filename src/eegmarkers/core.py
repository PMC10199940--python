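"""Core containers and scalp-montage metadata.

The unit of analysis throughout the package is one subject's multichannel
EEG segment: 19 channels placed according to the international 10-20
system, sampled at 128 Hz for 8 s (1,024 samples per channel) and
band-limited to 0.5-30 Hz. Subjects belong to one of four groups:

    A  healthy elderly, eyes open
    B  healthy elderly, eyes closed
    C  probable Alzheimer's disease (AD), eyes open
    D  probable AD, eyes closed

Group comparisons are only ever made within an eye condition
(A vs. C, B vs. D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 10-20 electrode order used for all records.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "T3", "T4", "T5", "T6", "O1", "O2",
)

GROUPS: tuple[str, ...] = ("A", "B", "C", "D")

#: Eye condition implied by each group label.
GROUP_EYE_CONDITION: dict[str, str] = {
    "A": "open", "B": "closed", "C": "open", "D": "closed",
}

#: Groups containing probable-AD subjects.
AD_GROUPS: frozenset[str] = frozenset({"C", "D"})

#: Canonical EEG rhythm names, slowest first.
BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


def validate_group(group: str) -> str:
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    return group


@dataclass
class EEGRecord:
    """One subject's EEG segment.

    Attributes
    ----------
    subject_id : str
        Unique identifier within a cohort.
    group : str
        One of ``A``, ``B``, ``C``, ``D``.
    channel_names : tuple of str
        Ordered electrode labels, a subset of :data:`CHANNELS_10_20`.
    signal : ndarray, shape (n_channels, T)
        Microvolt-scale samples, one row per channel.
    fs : float
        Sampling rate in Hz.
    """

    subject_id: str
    group: str
    channel_names: tuple[str, ...]
    signal: np.ndarray
    fs: float = 128.0
    eye_condition: str = field(init=False)

    def __post_init__(self) -> None:
        validate_group(self.group)
        self.eye_condition = GROUP_EYE_CONDITION[self.group]
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) == 0:
            raise ValueError("record must have at least one channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        unknown = [c for c in self.channel_names if c not in CHANNELS_10_20]
        if unknown:
            raise ValueError(f"channel names not in the 10-20 montage: {unknown}")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def is_ad(self) -> bool:
        return self.group in AD_GROUPS

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector for one electrode by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r} in record {self.subject_id}") from None
        return self.signal[idx]
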