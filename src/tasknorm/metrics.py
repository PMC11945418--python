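"""Validation metrics: peak preservation, onset/offset accuracy, smoothness,
grid-density (C) stability, and the rank-based comparison of the two
normalization versions.

Peak preservation quantifies how well the spline resampling keeps the
signal shape: for each repetition the position and amplitude of the
maximum and minimum are compared between the raw epoch and the
time-normalized one, mapped back to epoch seconds.  "Position" is
reported three ways — time delta (s), amplitude delta (uM), and the
2-component Euclidean norm on the (seconds, uM) pair without rescaling;
the Euclidean norm is what the C sweep uses as its error measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .epoching import Trial, TrialSet
from .model import logger
from .normalization import (
    NormalizedTrial,
    NormalizedTrialSet,
    normalize,
)

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PeakError:
    """Raw-vs-normalized extremum discrepancies, averaged over finite channels."""

    dt_max: float  # |time of maximum, raw - normalized|, s
    dt_min: float
    da_max: float  # |amplitude of maximum, raw - normalized|, uM
    da_min: float
    euclid: float  # mean Euclidean norm of the (dt, da) pairs, both extrema

    def __post_init__(self) -> None:
        for name in ("dt_max", "dt_min", "da_max", "da_min", "euclid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class VersionComparison:
    """Per-repetition indices and the paired rank test between versions."""

    smooth_v1: np.ndarray  # per-repetition smoothness index, version 1
    smooth_v2: np.ndarray
    onset_err: np.ndarray  # per-repetition |v2 - v1| onset percent
    offset_err: np.ndarray
    w_stat: float
    p_two_sided: float


def peak_preservation(trial: Trial, ntrial: NormalizedTrial) -> PeakError:
    """Compare extremum position and amplitude between a raw epoch and its
    normalized counterpart.

    The normalized grid is mapped back to epoch seconds through the
    trial's own seconds-per-grid-point vector, so time deltas are in the
    raw time frame.  Entirely-NaN channels are skipped with a warning.
    """
    if trial.values.shape[1:] != ntrial.values.shape[1:]:
        raise ValueError("trial and normalized trial have mismatched dimensions")
    n_ch, n_k = trial.values.shape[1:]
    dts_max, dts_min, das_max, das_min, euclids = [], [], [], [], []
    for ci in range(n_ch):
        for ki in range(n_k):
            raw = trial.values[:, ci, ki]
            norm = ntrial.values[:, ci, ki]
            if np.isnan(raw).all():
                logger.warning("peak_preservation: channel %d/%d is all-NaN, skipped",
                               ci, ki)
                continue
            i_max, i_min = int(np.argmax(raw)), int(np.argmin(raw))
            j_max, j_min = int(np.argmax(norm)), int(np.argmin(norm))
            dt_max = abs(trial.times[i_max] - ntrial.times_s[j_max])
            dt_min = abs(trial.times[i_min] - ntrial.times_s[j_min])
            da_max = abs(raw[i_max] - norm[j_max])
            da_min = abs(raw[i_min] - norm[j_min])
            dts_max.append(dt_max)
            dts_min.append(dt_min)
            das_max.append(da_max)
            das_min.append(da_min)
            euclids.append((math.hypot(dt_max, da_max) + math.hypot(dt_min, da_min)) / 2)
    if not euclids:
        raise ValueError("no finite channels to compare")
    return PeakError(
        dt_max=float(np.mean(dts_max)),
        dt_min=float(np.mean(dts_min)),
        da_max=float(np.mean(das_max)),
        da_min=float(np.mean(das_min)),
        euclid=float(np.mean(euclids)),
    )


def smoothness_index(values: np.ndarray) -> float:
    """Sample SD (n-1) of the first differences of a trace — lower is smoother.

    Differences are taken on the uniform normalized grid (unit index
    spacing), since the normalized axis is percent, not seconds.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("smoothness index needs at least 3 finite samples")
    return float(np.std(np.diff(v), ddof=1))


def _set_smoothness(nts: NormalizedTrialSet) -> np.ndarray:
    """Per-repetition smoothness, averaged over finite channel/chromophore traces."""
    out = []
    for t in nts.trials:
        vals = [
            smoothness_index(t.values[:, ci, ki])
            for ci in range(t.values.shape[1])
            for ki in range(t.values.shape[2])
            if not np.isnan(t.values[:, ci, ki]).all()
        ]
        out.append(float(np.mean(vals)))
    return np.asarray(out)


def onset_offset_table(
    v1: NormalizedTrialSet, v2: NormalizedTrialSet
) -> pd.DataFrame:
    """Per-repetition and summary onset/offset percentages for both versions.

    Version 1 places the task boundaries at fixed grid indices, so its SD
    rows are exactly zero; version 2's boundaries vary with repetition
    duration.
    """
    if v1.version != 1 or v2.version != 2:
        raise ValueError("expected a version-1 and a version-2 set, in that order")
    if v1.n_reps != v2.n_reps or v1.condition != v2.condition:
        raise ValueError("the two sets do not come from the same trials")
    rows = []
    for version, nts in ((1, v1), (2, v2)):
        for r, t in enumerate(nts.trials):
            rows.append((version, "rep", r + 1, t.onset_percent, t.offset_percent))
        on = np.array([t.onset_percent for t in nts.trials])
        off = np.array([t.offset_percent for t in nts.trials])
        rows.append((version, "mean", None, on.mean(), off.mean()))
        # SD computed on values shifted by the first element: identical
        # values then give exactly 0 (a floating-point mean would not)
        rows.append((version, "sd", None,
                     np.std(on - on[0], ddof=1), np.std(off - off[0], ddof=1)))
    return pd.DataFrame(
        rows,
        columns=["version", "statistic", "repetition", "onset_percent",
                 "offset_percent"],
    )


def wilcoxon_signed_rank(x: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (logged).  Ties among |differences| are
    midranked.  The two-sided p-value is exact — computed from the full
    null distribution of the positive-rank sum — for n <= 25, and uses
    the normal approximation with tie correction above that.  Returns
    ``(W, p)`` with ``W = min(W+, W-)``.
    """
    d = np.asarray(x, dtype=float)
    nz = d[d != 0]
    if nz.size < d.size:
        logger.info("wilcoxon: dropped %d zero difference(s)", d.size - nz.size)
    n = nz.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    w_stat = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_MAX_N:
        # distribution of W+ over all 2^n sign assignments, by convolution
        # on doubled ranks (midranks are multiples of 1/2)
        scaled = np.round(2 * ranks).astype(int)
        dist = np.zeros(scaled.sum() + 1)
        dist[0] = 1.0
        for s in scaled:
            shifted = np.zeros_like(dist)
            shifted[s:] = dist[: dist.size - s]
            dist = dist + shifted
        dist /= dist.sum()
        wp2 = int(round(2 * w_plus))
        lo = min(wp2, scaled.sum() - wp2)
        hi = max(wp2, scaled.sum() - wp2)
        p = float(dist[: lo + 1].sum() + dist[hi:].sum())
        return w_stat, min(1.0, p)

    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_corr
    z = (w_plus - mean) / math.sqrt(var)
    return w_stat, float(2 * stats.norm.sf(abs(z)))


def compare_versions(
    v1: NormalizedTrialSet, v2: NormalizedTrialSet
) -> VersionComparison:
    """Smoothness and onset/offset discrepancies between the two versions,
    with a Wilcoxon signed-rank test on the paired smoothness indices."""
    if v1.version != 1 or v2.version != 2:
        raise ValueError("expected a version-1 and a version-2 set, in that order")
    s1, s2 = _set_smoothness(v1), _set_smoothness(v2)
    onset_err = np.array(
        [abs(t.onset_percent - v1.onset_percent_final) for t in v2.trials]
    )
    offset_err = np.array(
        [abs(t.offset_percent - v1.offset_percent_final) for t in v2.trials]
    )
    w, p = wilcoxon_signed_rank(s1 - s2)
    return VersionComparison(
        smooth_v1=s1, smooth_v2=s2, onset_err=onset_err, offset_err=offset_err,
        w_stat=w, p_two_sided=p,
    )


@dataclass
class CSweepResult:
    """Mean peak-preservation error as a function of the grid constant C."""

    c_values: list[int]
    errors: list[float]  # mean Euclidean peak error over repetitions
    stable_c: int | None  # first C after which successive changes stay < 5%


def c_sweep(ts: TrialSet, c_values: list[int]) -> CSweepResult:
    """Run the normalization at each C and measure the peak-preservation error.

    The stability flag is the first C after which every successive
    relative change of the error curve stays below 5%.
    """
    if list(c_values) != sorted(c_values):
        raise ValueError("c_values must be sorted ascending")
    errors = []
    for c in c_values:
        cfg = replace(ts.config, C=int(c))
        sub = replace(ts, config=cfg)
        nts = normalize(sub)
        errs = [
            peak_preservation(trial, ntrial).euclid
            for trial, ntrial in zip(sub.trials, nts.trials)
        ]
        errors.append(float(np.mean(errs)))

    stable_c = None
    eps = 1e-15
    for k in range(len(errors)):
        ok = all(
            abs(errors[i + 1] - errors[i]) / max(abs(errors[i]), eps) < 0.05
            or abs(errors[i + 1] - errors[i]) < eps
            for i in range(k, len(errors) - 1)
        )
        if ok:
            stable_c = int(c_values[k])
            break
    return CSweepResult(c_values=[int(c) for c in c_values], errors=errors,
                        stable_c=stable_c)


def normality_p(x: np.ndarray) -> float:
    """Shapiro-Wilk normality p-value (report entry)."""
    return float(stats.shapiro(np.asarray(x, dtype=float)).pvalue)


def t_test_zero_p(x: np.ndarray) -> float:
    """One-sample t-test against zero mean (report entry)."""
    return float(stats.ttest_1samp(np.asarray(x, dtype=float), 0.0).pvalue)
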