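"""Core domain types for fNIRS concentration recordings.

A :class:`Recording` holds a continuous, pre-processed hemoglobin
concentration time series (micromolar) for a set of source-detector
channels and up to three chromophores (HbO2, HbR, HbT), together with
the stimulus events that mark task repetitions.  All downstream stages
(epoching, time-normalization, averaging) operate on these types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("tasknorm")

#: canonical chromophore axis order; missing chromophores are omitted
CHROMOPHORE_ORDER = ("HbO2", "HbR", "HbT")

#: accepted spellings (lower-cased) mapped to the canonical label
CHROMOPHORE_ALIASES = {
    "hbo": "HbO2",
    "hbo2": "HbO2",
    "hbr": "HbR",
    "hbt": "HbT",
}


def canonical_chromophore(label: str) -> str:
    """Map a chromophore spelling ("HbO", "hbo2", ...) to its canonical form."""
    try:
        return CHROMOPHORE_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown chromophore tag: {label!r}") from None


@dataclass(frozen=True)
class StimEvent:
    """One task repetition marker: onset and duration in seconds from recording start."""

    condition: str
    onset: float
    duration: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"stim onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"stim duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class ChannelInfo:
    """Source-detector pair bookkeeping (indices are 1-based as in SNIRF)."""

    source_index: int
    detector_index: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.source_index < 1 or self.detector_index < 1:
            raise ValueError("source/detector indices are 1-based and must be >= 1")
        if not self.label:
            object.__setattr__(
                self, "label", f"S{self.source_index}-D{self.detector_index}"
            )


@dataclass
class Recording:
    """Continuous concentration time series with stim events.

    Parameters
    ----------
    time : array, shape (n_samples,)
        Strictly increasing sample times in seconds.
    data : array, shape (n_samples, n_channels, n_chromophores)
        Concentration changes in micromolar.  A channel x chromophore
        column may be entirely NaN (pruned upstream); scattered NaN
        inside an otherwise finite column is rejected.
    chromophores : sequence of str
        Ordered subset of ``("HbO2", "HbR", "HbT")``.
    channels : list of ChannelInfo
    stims : list of StimEvent
    fs : float
        Nominal sampling rate in Hz.
    """

    time: np.ndarray
    data: np.ndarray
    chromophores: tuple[str, ...]
    channels: list[ChannelInfo]
    stims: list[StimEvent] = field(default_factory=list)
    fs: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.chromophores = tuple(self.chromophores)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        if self.data.ndim != 3:
            raise ValueError("data must be (n_samples, n_channels, n_chromophores)")
        if self.data.shape[0] != self.time.size:
            raise ValueError("data and time lengths differ")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("data channel axis does not match channel list")
        if self.data.shape[2] != len(self.chromophores):
            raise ValueError("data chromophore axis does not match chromophore list")
        order = [c for c in CHROMOPHORE_ORDER if c in self.chromophores]
        if list(self.chromophores) != order:
            raise ValueError(
                f"chromophores must follow canonical order {CHROMOPHORE_ORDER}, "
                f"got {self.chromophores}"
            )
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time vector must be strictly increasing")
        keys = {(c.source_index, c.detector_index) for c in self.channels}
        if len(keys) != len(self.channels):
            raise ValueError("duplicate (source, detector) pair in channel list")
        if self.fs <= 0:
            if self.time.size < 2:
                raise ValueError("fs must be given for single-sample recordings")
            self.fs = 1.0 / float(np.median(np.diff(self.time)))
        elif self.time.size >= 2:
            med = float(np.median(np.diff(self.time)))
            if not math.isclose(med, 1.0 / self.fs, rel_tol=0.01):
                raise ValueError(
                    f"median sample spacing {med:.6g} s inconsistent with fs={self.fs} Hz"
                )
        self._check_nan_policy()

    def _check_nan_policy(self) -> None:
        # entirely-NaN columns model channels pruned upstream and are allowed;
        # scattered NaN would be silently interpolated over, so it is an error
        nan = np.isnan(self.data)
        per_col = nan.sum(axis=0)
        bad = (per_col > 0) & (per_col < self.data.shape[0])
        if np.any(bad):
            ch, chrom = np.argwhere(bad)[0]
            raise ValueError(
                "scattered NaN within channel "
                f"{self.channels[ch].label}:{self.chromophores[chrom]}; "
                "only fully pruned (all-NaN) channels are accepted"
            )
        for ch, chrom in np.argwhere(per_col == self.data.shape[0]):
            logger.warning(
                "channel %s:%s is entirely NaN (pruned); it will be carried "
                "through and excluded from metrics",
                self.channels[ch].label,
                self.chromophores[chrom],
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def conditions(self) -> list[str]:
        """Distinct stim condition labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.stims:
            seen.setdefault(s.condition, None)
        return list(seen)

    def stims_for(self, condition: str) -> list[StimEvent]:
        """Stim events of one condition sorted by onset."""
        return sorted(
            (s for s in self.stims if s.condition == condition),
            key=lambda s: s.onset,
        )


@dataclass(frozen=True)
class NormalizationConfig:
    """User parameters of the time-normalization.

    ``deltat_base`` and ``deltat_post`` are the baseline and post-task
    durations in seconds bounding each epoch around the task interval.
    ``C`` is the grid density constant (samples per second of nominal
    duration); the number of normalized samples per phase is
    ``round(C * duration)``.  ``version`` selects phase-wise (1) or
    whole-trial (2) interpolation.
    """

    deltat_base: float = 2.0
    deltat_post: float = 3.0
    C: int = 50
    version: int = 1
    show: int = 0

    def __post_init__(self) -> None:
        if self.deltat_base <= 0:
            raise ValueError("deltat_base must be > 0: baseline correction needs a baseline")
        if self.deltat_post < 0:
            raise ValueError("deltat_post must be >= 0")
        if int(self.C) != self.C or self.C < 1:
            raise ValueError("C must be an integer >= 1")
        if self.version not in (1, 2):
            raise ValueError("version must be 1 or 2")
        if self.show not in (0, 1):
            raise ValueError("show must be 0 or 1")

    @property
    def deltat(self) -> tuple[float, float]:
        return (self.deltat_base, self.deltat_post)
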