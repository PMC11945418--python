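"""Segmentation of the continuous signal into per-repetition epochs.

Each epoch spans ``[onset - deltat_base, onset + duration + deltat_post]``
in recording time and is split conceptually into three phases: baseline,
task and post-task.  Phase boundaries are kept as continuous seconds; no
resampling happens here — the spline stage defines the output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NormalizationConfig, Recording, StimEvent, logger

#: minimum raw samples per nonzero-duration phase, needed for a cubic fit
MIN_PHASE_SAMPLES = 4


@dataclass
class Trial:
    """One epoch: local time (0 at epoch start), values, and phase boundaries."""

    times: np.ndarray  # seconds, 0 at epoch start
    values: np.ndarray  # (n_local_samples, n_channels, n_chromophores), uM
    onset_s: float  # epoch start -> task onset (= deltat_base)
    offset_s: float  # epoch start -> task offset

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (0 < self.onset_s < self.offset_s):
            raise ValueError("need 0 < onset_s < offset_s")
        # the nominal offset may overshoot the last retained sample by less
        # than one sample period (continuous boundaries vs discrete sampling)
        dt = float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.0
        if self.offset_s > self.times[-1] + dt:
            raise ValueError("task offset falls outside the epoch")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def epoch_length_s(self) -> float:
        return float(self.times[-1])

    def phase_slices(self) -> dict[str, np.ndarray]:
        """Boolean masks of samples per phase (closed intervals, shared boundaries)."""
        t = self.times
        eps = 1e-9
        return {
            "baseline": (t >= -eps) & (t <= self.onset_s + eps),
            "task": (t >= self.onset_s - eps) & (t <= self.offset_s + eps),
            "post": (t >= self.offset_s - eps),
        }


@dataclass
class TrialSet:
    """All repetitions of one condition plus the mean task duration m."""

    condition: str
    trials: list[Trial]
    config: NormalizationConfig
    channel_labels: list[str] = field(default_factory=list)
    chromophores: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.trials) < 2:
            raise ValueError(
                "the algorithm requires a minimum of two repetitions"
            )
        shapes = {t.values.shape[1:] for t in self.trials}
        if len(shapes) != 1:
            raise ValueError("trials have mismatched channel/chromophore dimensions")

    @property
    def m(self) -> float:
        """Mean task duration over repetitions, seconds."""
        return float(np.mean([t.duration_s for t in self.trials]))

    @property
    def n_reps(self) -> int:
        return len(self.trials)


def extract_trials(
    rec: Recording, condition: str, config: NormalizationConfig
) -> TrialSet:
    """Cut one epoch per stim event of ``condition`` out of the recording.

    Epochs that would extend past the recording edges are dropped with a
    warning rather than zero-padded (padding would fabricate baseline data
    that baseline correction later relies on).  Raises if fewer than two
    epochs survive, or if any phase with nonzero nominal duration has
    fewer than four raw samples (cubic interpolation needs four knots).
    """
    stims = rec.stims_for(condition)
    if not stims:
        raise ValueError(
            f"unknown condition {condition!r}; available: {rec.conditions()}"
        )
    if len(stims) < 2:
        raise ValueError("the algorithm requires a minimum of two repetitions")

    trials: list[Trial] = []
    prev_end = None
    for k, stim in enumerate(stims):
        start = stim.onset - config.deltat_base
        end = stim.onset + stim.duration + config.deltat_post
        if start < rec.time[0] - 1e-9 or end > rec.time[-1] + 1e-9:
            logger.warning(
                "repetition %d of %r spans [%.3f, %.3f] s, outside the "
                "recording [%.3f, %.3f] s; dropped",
                k + 1, condition, start, end, rec.time[0], rec.time[-1],
            )
            continue
        if prev_end is not None and start < prev_end - 1e-9:
            logger.warning(
                "epoch %d of %r overlaps the previous epoch's post-task window "
                "(baseline starts at %.3f s, previous epoch ends at %.3f s)",
                k + 1, condition, start, prev_end,
            )
        prev_end = end

        mask = (rec.time >= start - 1e-9) & (rec.time <= end + 1e-9)
        trial = Trial(
            times=rec.time[mask] - start,
            values=rec.data[mask],
            onset_s=config.deltat_base,
            offset_s=config.deltat_base + stim.duration,
        )
        _check_phase_samples(trial, config, condition, k + 1)
        trials.append(trial)

    if len(trials) < 2:
        raise ValueError("the algorithm requires a minimum of two repetitions")
    return TrialSet(
        condition=condition,
        trials=trials,
        config=config,
        channel_labels=[c.label for c in rec.channels],
        chromophores=rec.chromophores,
    )


def _check_phase_samples(
    trial: Trial, config: NormalizationConfig, condition: str, rep: int
) -> None:
    nominal = {
        "baseline": config.deltat_base,
        "task": trial.duration_s,
        "post": config.deltat_post,
    }
    for phase, mask in trial.phase_slices().items():
        if nominal[phase] > 0 and int(mask.sum()) < MIN_PHASE_SAMPLES:
            raise ValueError(
                f"repetition {rep} of {condition!r}: {phase} phase has only "
                f"{int(mask.sum())} samples; at least {MIN_PHASE_SAMPLES} are "
                "needed for cubic interpolation"
            )


def pair_markers(
    events: list[StimEvent], condition: str | None = None
) -> list[StimEvent]:
    """Convert EMG-style start/stop marker pairs into duration-carrying events.

    Consecutive markers are paired in onset order: the first of each pair
    marks the task onset, the second the offset.  An odd marker count is
    an error (an unpaired marker cannot define a duration).
    """
    sel = sorted(
        (e for e in events if condition is None or e.condition == condition),
        key=lambda e: e.onset,
    )
    if len(sel) % 2:
        raise ValueError(f"unpaired marker at onset {sel[-1].onset} s")
    out = []
    for start, stop in zip(sel[::2], sel[1::2]):
        out.append(
            StimEvent(start.condition, start.onset, stop.onset - start.onset,
                      start.amplitude)
        )
    return out
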