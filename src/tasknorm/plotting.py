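"""Per-channel HRF figures: mean +/- SD band with per-repetition traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by default; `show` switches to interactive
import matplotlib.pyplot as plt
import numpy as np

from .averaging import HRF, correct_trials
from .normalization import NormalizedTrialSet

_PLOT_CHROMS = ("HbO2", "HbR")
_COLORS = {"HbO2": "tab:red", "HbR": "tab:blue"}


def plot_hrf(
    hrf: HRF,
    nts: NormalizedTrialSet,
    out_dir: str | Path,
    show: bool = False,
    fmt: str = "png",
) -> list[Path]:
    """One figure per channel: averaged HRF on top, per-repetition HbO2 and
    HbR traces below, with vertical onset/offset markers.

    Per-repetition traces are shown baseline-corrected individually so
    they sit near zero at rest, mirroring how the averaged trace is
    presented.  Returns the written file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shown = correct_trials(nts)
    paths = []
    chroms = [c for c in _PLOT_CHROMS if c in hrf.chromophores]
    for ci, label in enumerate(hrf.channel_labels):
        fig, axes = plt.subplots(1 + len(chroms), 1, figsize=(7, 8), sharex=True)
        axes = np.atleast_1d(axes)
        ax = axes[0]
        for chrom in chroms:
            ki = hrf.chromophores.index(chrom)
            m, s = hrf.mean[:, ci, ki], hrf.sd[:, ci, ki]
            ax.plot(hrf.percent, m, color=_COLORS[chrom], label=chrom)
            ax.fill_between(hrf.percent, m - s, m + s, color=_COLORS[chrom], alpha=0.2)
        _markers(ax, hrf.onset_percent, hrf.offset_percent)
        ax.set_title(f"{label} — mean HRF ± SD ({hrf.n_reps} repetitions)")
        ax.set_ylabel("Δ concentration (µM)")
        ax.legend(loc="upper right", fontsize=8)

        for row, chrom in enumerate(chroms, start=1):
            ki = hrf.chromophores.index(chrom)
            ax = axes[row]
            for t in shown.trials:
                ax.plot(t.percent, t.values[:, ci, ki], lw=0.8, alpha=0.7)
            _markers(ax, hrf.onset_percent, hrf.offset_percent)
            ax.set_ylabel(f"{chrom} per rep (µM)")
        axes[-1].set_xlabel("% of trial")
        fig.tight_layout()
        path = out_dir / f"hrf_{label}.{fmt}"
        fig.savefig(path, dpi=120)
        paths.append(path)
        if show:  # pragma: no cover - interactive only
            plt.show()
        plt.close(fig)
    return paths


def _markers(ax, onset: float, offset: float) -> None:
    ax.axvline(onset, color="k", ls="--", lw=0.8)
    ax.axvline(offset, color="k", ls="--", lw=0.8)
    ax.axhline(0.0, color="k", lw=0.5, alpha=0.5)
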