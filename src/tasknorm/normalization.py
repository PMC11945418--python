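"""Core time-normalization: spline resampling onto a fixed percent-of-trial grid.

Each task repetition (epoch) is mapped onto a common axis where 0% is the
epoch start and 100% the epoch end, so that repetitions of unequal
duration become comparable and can be averaged point-by-point.

Two variants are provided:

* **version 1** (phase-wise): baseline, task and post-task are resampled
  separately — ``round(C * deltat)`` points for the fixed-length phases,
  ``round(C * m)`` for the task, with ``m`` the mean task duration over
  repetitions — and reassembled.  The task onset/offset then fall at the
  same grid index in every repetition, so their percent positions have
  exactly zero spread.
* **version 2** (whole-trial): each epoch is resampled in a single pass
  onto ``round(C * (deltat_base + m + deltat_post))`` points.  Onset and
  offset percentages vary with each repetition's duration; the final
  values are the across-repetition averages.

Splines are cubic with not-a-knot end conditions and pass through every
raw sample exactly, which is what preserves the signal shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .epoching import MIN_PHASE_SAMPLES, Trial, TrialSet
from .model import NormalizationConfig


@dataclass
class NormalizedTrial:
    """One repetition on the 0-100% grid.

    ``times_s`` keeps, for each grid point, the corresponding instant in
    the repetition's own epoch seconds — the inverse of the
    seconds-to-percent map, needed to compare peak positions against the
    raw signal.
    """

    percent: np.ndarray  # (n_grid,), 0..100
    values: np.ndarray  # (n_grid, n_channels, n_chromophores), uM
    onset_percent: float
    offset_percent: float
    times_s: np.ndarray  # (n_grid,), epoch seconds per grid point

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if not (abs(self.percent[0]) < 1e-12 and abs(self.percent[-1] - 100) < 1e-9):
            raise ValueError("percent grid must span 0..100")
        if np.any(np.diff(self.percent) <= 0):
            raise ValueError("percent grid must be strictly increasing")
        if not (0 < self.onset_percent < self.offset_percent <= 100):
            raise ValueError("need 0 < onset% < offset% <= 100")


@dataclass
class NormalizedTrialSet:
    """All repetitions of a condition on one common percent grid."""

    condition: str
    trials: list[NormalizedTrial]
    version: int
    onset_percent_final: float
    offset_percent_final: float
    config: NormalizationConfig
    channel_labels: list[str] = field(default_factory=list)
    chromophores: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        grids = {t.percent.shape[0] for t in self.trials}
        if len(grids) != 1:
            raise ValueError("repetitions ended up on different grid sizes")
        ref = self.trials[0].percent
        for t in self.trials[1:]:
            if not np.allclose(t.percent, ref, atol=1e-12):
                raise ValueError("repetitions ended up on different percent grids")

    @property
    def percent(self) -> np.ndarray:
        return self.trials[0].percent

    @property
    def n_grid(self) -> int:
        return self.trials[0].percent.size

    @property
    def n_reps(self) -> int:
        return len(self.trials)


def sample_counts(
    config: NormalizationConfig, m: float
) -> tuple[int, int, int]:
    """Normalized sample counts per phase: ``round(C * duration)``.

    Rounding is round-half-to-even.  Any phase with nonzero nominal
    duration must receive at least four points; otherwise C is too small.
    """
    if m <= 0:
        raise ValueError("mean task duration m must be > 0")
    counts = (
        int(np.round(config.C * config.deltat_base)),
        int(np.round(config.C * m)),
        int(np.round(config.C * config.deltat_post)),
    )
    durations = (config.deltat_base, m, config.deltat_post)
    for name, d, n in zip(("baseline", "task", "post-task"), durations, counts):
        if d > 0 and n < MIN_PHASE_SAMPLES:
            raise ValueError(
                f"{name} phase would get only {n} normalized samples; increase C"
            )
    return counts


def spline_resample(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Cubic not-a-knot spline through (x, y), evaluated at xq.

    ``y`` may be multi-dimensional; interpolation runs along axis 0.
    Queries may overshoot the knot range by up to one knot spacing — the
    knots are a discrete sampling of a continuous phase whose nominal
    boundary generally falls between samples — in which case the end
    cubic is extended.  Anything beyond that is genuine extrapolation and
    an error.
    """
    x = np.asarray(x, dtype=float)
    xq = np.asarray(xq, dtype=float)
    if x.size < MIN_PHASE_SAMPLES:
        raise ValueError(
            f"cubic spline needs at least {MIN_PHASE_SAMPLES} knots, got {x.size}"
        )
    tol = float(np.median(np.diff(x)))
    if np.any(xq < x[0] - tol) or np.any(xq > x[-1] + tol):
        raise ValueError("query points outside the knot range (extrapolation)")
    y = np.asarray(y, dtype=float)
    flat = y.reshape(y.shape[0], -1)
    all_nan = np.isnan(flat).all(axis=0)
    if not all_nan.any():
        return CubicSpline(x, y, axis=0, bc_type="not-a-knot")(xq)
    # pruned (all-NaN) channels are carried through as NaN; finite columns
    # are interpolated normally
    out = np.full((xq.size, flat.shape[1]), np.nan)
    finite = ~all_nan
    if finite.any():
        out[:, finite] = CubicSpline(
            x, flat[:, finite], axis=0, bc_type="not-a-knot"
        )(xq)
    return out.reshape((xq.size,) + y.shape[1:])


def _phase_grid(start: float, end: float, n: int) -> np.ndarray:
    """n evenly spaced points covering [start, end) — half-open phase convention."""
    return start + (end - start) * np.arange(n) / n


def normalize_v1(ts: TrialSet) -> NormalizedTrialSet:
    """Phase-wise normalization: resample baseline/task/post separately, reassemble.

    Phases are concatenated on a half-open convention — each phase
    contributes points over ``[start, end)`` of its own span, and the
    single terminal point (epoch end) is appended — so the reassembled
    grid has ``n_base + n_task + n_post + 1`` points and no duplicated
    abscissae.  Onset/offset land on fixed grid indices, identical for
    every repetition.
    """
    cfg = ts.config
    n_base, n_task, n_post = sample_counts(cfg, ts.m)
    n_grid = n_base + n_task + n_post + 1
    percent = 100.0 * np.arange(n_grid) / (n_grid - 1)
    onset_pct = 100.0 * n_base / (n_grid - 1)
    offset_pct = 100.0 * (n_base + n_task) / (n_grid - 1)

    out = []
    for r, trial in enumerate(ts.trials):
        end = trial.offset_s + cfg.deltat_post  # nominal epoch end
        bounds = [
            ("baseline", 0.0, trial.onset_s, n_base),
            ("task", trial.onset_s, trial.offset_s, n_task),
            ("post", trial.offset_s, end, n_post),
        ]
        masks = trial.phase_slices()
        tq_parts, val_parts = [], []
        for phase, p0, p1, n in bounds:
            if n == 0:
                continue
            tq = _phase_grid(p0, p1, n)
            x = trial.times[masks[phase]]
            if x.size < MIN_PHASE_SAMPLES:
                raise ValueError(
                    f"repetition {r + 1}, {phase} phase: only {x.size} raw "
                    f"samples, need {MIN_PHASE_SAMPLES} for cubic interpolation"
                )
            y = trial.values[masks[phase]]
            val_parts.append(spline_resample(x, y, tq))
            tq_parts.append(tq)
        # terminal point belongs to the last nonempty phase
        last_mask = masks["post"] if n_post else masks["task"]
        x = trial.times[last_mask]
        y = trial.values[last_mask]
        tq_parts.append(np.array([end]))
        val_parts.append(spline_resample(x, y, np.array([end])))

        out.append(
            NormalizedTrial(
                percent=percent,
                values=np.concatenate(val_parts, axis=0),
                onset_percent=onset_pct,
                offset_percent=offset_pct,
                times_s=np.concatenate(tq_parts),
            )
        )

    return NormalizedTrialSet(
        condition=ts.condition,
        trials=out,
        version=1,
        onset_percent_final=onset_pct,
        offset_percent_final=offset_pct,
        config=cfg,
        channel_labels=ts.channel_labels,
        chromophores=ts.chromophores,
    )


def normalize_v2(ts: TrialSet) -> NormalizedTrialSet:
    """Whole-trial normalization: one spline per epoch, one pass, one grid.

    Each repetition's onset/offset percent depends on its own duration;
    the set-level values are the averages over repetitions.
    """
    cfg = ts.config
    total = cfg.deltat_base + ts.m + cfg.deltat_post
    n_grid = int(np.round(cfg.C * total))
    if n_grid < MIN_PHASE_SAMPLES:
        raise ValueError(
            f"whole-trial grid would have only {n_grid} samples; increase C"
        )
    percent = np.linspace(0.0, 100.0, n_grid)

    out = []
    onsets, offsets = [], []
    for r, trial in enumerate(ts.trials):
        span = cfg.deltat_base + trial.duration_s + cfg.deltat_post
        tq = span * percent / 100.0
        x, y = trial.times, trial.values
        if x.size < MIN_PHASE_SAMPLES:
            raise ValueError(f"repetition {r + 1}: too few raw samples")
        vals = spline_resample(x, y, tq)
        on = 100.0 * cfg.deltat_base / span
        off = 100.0 * (cfg.deltat_base + trial.duration_s) / span
        onsets.append(on)
        offsets.append(off)
        out.append(
            NormalizedTrial(percent=percent, values=vals, onset_percent=on,
                            offset_percent=off, times_s=tq)
        )

    return NormalizedTrialSet(
        condition=ts.condition,
        trials=out,
        version=2,
        onset_percent_final=float(np.mean(onsets)),
        offset_percent_final=float(np.mean(offsets)),
        config=cfg,
        channel_labels=ts.channel_labels,
        chromophores=ts.chromophores,
    )


def normalize(ts: TrialSet) -> NormalizedTrialSet:
    """Dispatch on the configured algorithm version."""
    return normalize_v1(ts) if ts.config.version == 1 else normalize_v2(ts)
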