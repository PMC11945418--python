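"""Block averaging across normalized repetitions and baseline correction.

The averaged trace is the point-by-point mean over repetitions on the
common percent grid, with the sample standard deviation (n-1 denominator)
as a spread estimate.  Baseline correction subtracts, per channel and
chromophore, the mean of the pre-task segment from the whole trace, so
the response is expressed relative to rest (0 uM on average during the
baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import NormalizationConfig
from .normalization import NormalizedTrialSet


@dataclass
class HRF:
    """Across-repetition mean (+/- SD) response on the percent-of-trial grid."""

    percent: np.ndarray
    mean: np.ndarray  # (n_grid, n_channels, n_chromophores), uM
    sd: np.ndarray  # same shape, uM
    onset_percent: float
    offset_percent: float
    n_reps: int
    baseline_corrected: bool = False
    condition: str = ""
    channel_labels: list[str] = field(default_factory=list)
    chromophores: tuple[str, ...] = ()
    config: NormalizationConfig | None = None

    def baseline_mask(self) -> np.ndarray:
        """Grid points strictly before the task onset (the onset point is task)."""
        return self.percent < self.onset_percent

    def task_mask(self) -> np.ndarray:
        return (self.percent >= self.onset_percent) & (
            self.percent <= self.offset_percent
        )


def block_average(nts: NormalizedTrialSet) -> HRF:
    """Point-wise mean and sample SD over repetitions, per channel/chromophore."""
    stack = np.stack([t.values for t in nts.trials], axis=0)
    return HRF(
        percent=nts.percent.copy(),
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        onset_percent=nts.onset_percent_final,
        offset_percent=nts.offset_percent_final,
        n_reps=nts.n_reps,
        baseline_corrected=False,
        condition=nts.condition,
        channel_labels=list(nts.channel_labels),
        chromophores=nts.chromophores,
        config=nts.config,
    )


def baseline_correct(hrf: HRF) -> HRF:
    """Subtract the baseline-segment mean from the whole mean trace.

    Shift-only: the SD is untouched.  Applying the correction twice is an
    error, as is an empty baseline segment.
    """
    if hrf.baseline_corrected:
        raise ValueError("HRF is already baseline-corrected")
    mask = hrf.baseline_mask()
    if not mask.any():
        raise ValueError("baseline segment is empty; cannot correct")
    shift = hrf.mean[mask].mean(axis=0, keepdims=True)
    return replace(
        hrf,
        mean=hrf.mean - shift,
        sd=hrf.sd.copy(),
        percent=hrf.percent.copy(),
        baseline_corrected=True,
    )


def correct_trials(nts: NormalizedTrialSet) -> NormalizedTrialSet:
    """Per-repetition baseline correction, for per-repetition display only.

    The standard pipeline corrects the averaged trace; this variant shifts
    each repetition by its own baseline mean so that individual traces sit
    near zero at rest in plots.
    """
    out = []
    for t in nts.trials:
        mask = t.percent < t.onset_percent
        shift = t.values[mask].mean(axis=0, keepdims=True)
        out.append(replace(t, values=t.values - shift))
    return replace(nts, trials=out)
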