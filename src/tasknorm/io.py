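"""Readers and writers: SNIRF concentration files, delimited-text fallback, HRF output.

The SNIRF reader accepts any data block whose measurement list carries
concentration dataTypeLabels (HbO/HbO2, HbR, HbT, case-insensitive) and
logs which block was used.  Raw-intensity-only files are rejected:
conversion to concentration happens upstream.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import TYPE_CHECKING

import h5py
import numpy as np
import pandas as pd

from .model import (
    CHROMOPHORE_ORDER,
    CHROMOPHORE_ALIASES,
    ChannelInfo,
    Recording,
    StimEvent,
    canonical_chromophore,
    logger,
)

if TYPE_CHECKING:  # pragma: no cover
    from .averaging import HRF

_CHANNEL_RE = re.compile(r"^S(\d+)[-_]?D(\d+)$", re.IGNORECASE)


def _h5_scalar(ds) -> str | float:
    v = ds[()] if isinstance(ds, h5py.Dataset) else ds
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray) and v.size == 1:
        v = v.reshape(-1)[0]
        return v.decode() if isinstance(v, bytes) else v
    return v


def read_snirf(path: str | Path) -> Recording:
    """Read a SNIRF (HDF5) file containing concentration data and stim events.

    Returns a :class:`Recording` whose chromophore axis follows the
    canonical HbO2, HbR, HbT order (missing chromophores omitted).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs_names = sorted(k for k in f if k == "nirs" or k.startswith("nirs"))
        if not nirs_names:
            raise ValueError(f"{path}: not a SNIRF file (no /nirs group)")
        nirs = f[nirs_names[0]]

        time_factor = 1.0
        meta = nirs.get("metaDataTags")
        if meta is not None and "TimeUnit" in meta:
            unit = str(_h5_scalar(meta["TimeUnit"])).strip().lower()
            if unit in ("ms", "millisecond", "milliseconds"):
                time_factor = 1e-3

        block_names = sorted(
            (k for k in nirs if re.fullmatch(r"data\d*", k)),
            key=lambda k: (len(k), k),
        )
        chosen = None
        for name in block_names:
            ml = _measurement_list(nirs[name])
            if ml and any(m["label"] is not None for m in ml):
                chosen = (name, ml)
                break
        if chosen is None:
            raise ValueError(
                f"{path}: no concentration data; run conversion upstream"
            )
        block_name, ml = chosen
        logger.info("read_snirf: using data block /%s/%s", nirs_names[0], block_name)
        block = nirs[block_name]

        time = np.asarray(block["time"][()], dtype=float).reshape(-1) * time_factor
        series = np.asarray(block["dataTimeSeries"][()], dtype=float)
        if series.ndim == 1:
            series = series[:, None]
        if time.size == 2 and series.shape[0] > 2:
            # SNIRF "start, step" shorthand for a regular time axis
            start, step = time
            time = start + step * np.arange(series.shape[0])
        if np.any(np.diff(time) <= 0):
            raise ValueError(f"{path}: time vector is not strictly increasing")

        channels: list[ChannelInfo] = []
        ch_index: dict[tuple[int, int], int] = {}
        present: set[str] = set()
        cols: list[tuple[int, str, int]] = []  # (channel idx, chromophore, column)
        for m in ml:
            if m["label"] is None:
                continue
            key = (m["source"], m["detector"])
            if key not in ch_index:
                ch_index[key] = len(channels)
                channels.append(ChannelInfo(*key))
            present.add(m["label"])
            cols.append((ch_index[key], m["label"], m["column"]))

        chroms = tuple(c for c in CHROMOPHORE_ORDER if c in present)
        data = np.full((time.size, len(channels), len(chroms)), np.nan)
        for ch, label, col in cols:
            data[:, ch, chroms.index(label)] = series[:, col]

        stims: list[StimEvent] = []
        for name in sorted(k for k in nirs if re.fullmatch(r"stim\d*", k)):
            g = nirs[name]
            cond = str(_h5_scalar(g["name"])) if "name" in g else name
            rows = np.atleast_2d(np.asarray(g["data"][()], dtype=float))
            if rows.size == 0:
                continue
            for row in rows:
                onset = float(row[0]) * time_factor
                dur = float(row[1]) * time_factor if row.size > 1 else 1.0
                amp = float(row[2]) if row.size > 2 else 1.0
                stims.append(StimEvent(cond, onset, dur, amp))
        if not stims:
            raise ValueError(f"{path}: no trigger information")

    return Recording(time=time, data=data, chromophores=chroms,
                     channels=channels, stims=stims)


def _measurement_list(block: h5py.Group) -> list[dict]:
    """Parse measurementList1..N; label is None for non-concentration entries."""
    out = []
    for key in sorted(
        (k for k in block if re.fullmatch(r"measurementList\d+", k)),
        key=lambda k: int(k[len("measurementList"):]),
    ):
        g = block[key]
        label = None
        if "dataTypeLabel" in g:
            raw = str(_h5_scalar(g["dataTypeLabel"])).strip().lower()
            label = CHROMOPHORE_ALIASES.get(raw)
        out.append(
            {
                "column": int(key[len("measurementList"):]) - 1,
                "source": int(_h5_scalar(g["sourceIndex"])),
                "detector": int(_h5_scalar(g["detectorIndex"])),
                "label": label,
            }
        )
    return out


def read_text(path: str | Path, trigger_path: str | Path) -> Recording:
    """Read the delimited-text fallback format.

    ``path`` is a tab-separated table whose first column is time in
    seconds and whose remaining columns are named ``<channel>:<chromophore>``
    (e.g. ``S1-D2:HbO2``).  ``trigger_path`` is a tab-separated table with
    columns condition, onset, duration and optionally amplitude.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated column names {dupes}")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: time not strictly increasing")

    channels: list[ChannelInfo] = []
    ch_index: dict[str, int] = {}
    present: set[str] = set()
    parsed: list[tuple[int, str, str]] = []
    for col in df.columns[1:]:
        try:
            ch_label, chrom_tag = col.rsplit(":", 1)
        except ValueError:
            raise ValueError(f"{path}: column {col!r} is not '<channel>:<chromophore>'")
        chrom = canonical_chromophore(chrom_tag)
        if ch_label not in ch_index:
            m = _CHANNEL_RE.match(ch_label)
            if m:
                info = ChannelInfo(int(m.group(1)), int(m.group(2)), ch_label)
            else:
                info = ChannelInfo(len(channels) + 1, len(channels) + 1, ch_label)
            ch_index[ch_label] = len(channels)
            channels.append(info)
        present.add(chrom)
        parsed.append((ch_index[ch_label], chrom, col))

    chroms = tuple(c for c in CHROMOPHORE_ORDER if c in present)
    data = np.full((time.size, len(channels), len(chroms)), np.nan)
    for ch, chrom, col in parsed:
        data[:, ch, chroms.index(chrom)] = df[col].to_numpy(dtype=float)

    trig = pd.read_csv(trigger_path, sep="\t")
    if trig.empty:
        raise ValueError(f"{trigger_path}: no trigger information")
    stims = [
        StimEvent(
            str(r["condition"]),
            float(r["onset"]),
            float(r["duration"]),
            float(r.get("amplitude", 1.0)),
        )
        for _, r in trig.iterrows()
    ]
    return Recording(time=time, data=data, chromophores=chroms,
                     channels=channels, stims=stims)


def write_text(rec: Recording, path: str | Path, trigger_path: str | Path) -> None:
    """Write a Recording in the delimited-text fallback format (inverse of read_text)."""
    cols = {"time": rec.time}
    for ci, ch in enumerate(rec.channels):
        for ki, chrom in enumerate(rec.chromophores):
            cols[f"{ch.label}:{chrom}"] = rec.data[:, ci, ki]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g",
                              lineterminator="\n")
    trig = pd.DataFrame(
        [
            {"condition": s.condition, "onset": s.onset, "duration": s.duration,
             "amplitude": s.amplitude}
            for s in rec.stims
        ]
    )
    trig.to_csv(trigger_path, sep="\t", index=False, float_format="%.17g",
                lineterminator="\n")


def write_hrf(hrf: "HRF", path: str | Path) -> None:
    """Write an HRF as TSV (percent, channel, chromophore, mean, sd) plus a JSON sidecar.

    Values are printed with 17 significant digits so a write-then-parse
    round trip is lossless at double precision.  The sidecar (same stem,
    ``.json``) records onset/offset percentages, repetition count and the
    normalization configuration.
    """
    path = Path(path)
    if not np.all(np.isfinite(hrf.percent)):
        raise ValueError("HRF percent grid must be finite")
    rows = []
    for gi, pct in enumerate(hrf.percent):
        for ci, ch in enumerate(hrf.channel_labels):
            for ki, chrom in enumerate(hrf.chromophores):
                rows.append((pct, ch, chrom, hrf.mean[gi, ci, ki], hrf.sd[gi, ci, ki]))
    df = pd.DataFrame(rows, columns=["percent", "channel", "chromophore", "mean", "sd"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")

    sidecar = {
        "onset_percent": hrf.onset_percent,
        "offset_percent": hrf.offset_percent,
        "n_reps": hrf.n_reps,
        "baseline_corrected": hrf.baseline_corrected,
        "config": {
            "deltat": list(hrf.config.deltat),
            "C": hrf.config.C,
            "version": hrf.config.version,
        }
        if hrf.config is not None
        else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_hrf(path: str | Path) -> pd.DataFrame:
    """Parse an HRF TSV back into a long-format DataFrame (round-trip helper)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
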