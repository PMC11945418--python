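"""Seeded generator of synthetic multi-repetition fNIRS concentration recordings.

The generator emulates a self-paced motor protocol: a participant repeats
a task several times at their own pace, so trial durations vary from
repetition to repetition (drawn from a truncated normal with a stated
mean and SD, e.g. 6.60 +/- 1.30 s for overground walking).  The evoked
response is a canonical double-gamma kernel (peak ~6 s, undershoot ~16 s)
convolved with the task boxcar; HbR mirrors HbO2 with a negative ratio
and a 1 s delay; HbT is their sum.  Physiological nuisance terms cover
the standard fNIRS bands: cardiac (~1 Hz), respiration (~0.25 Hz), Mayer
waves (~0.1 Hz), slow linear drift, and white sensor noise.

Everything is reproducible from the seed: the same SimParams give a
bit-identical Recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.stats import truncnorm

from .model import ChannelInfo, NormalizationConfig, Recording, StimEvent


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes (uM) and frequencies (Hz) of the physiological nuisance model."""

    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.05
    resp_hz: float = 0.25
    resp_amp: float = 0.05
    mayer_hz: float = 0.1
    mayer_amp: float = 0.08
    drift_per_min: float = 0.02  # uM per minute, linear
    white_sd: float = 0.03  # uM

    @classmethod
    def zero(cls) -> "NoiseParams":
        return cls(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
                   drift_per_min=0.0, white_sd=0.0)

    def scaled(self, factor: float) -> "NoiseParams":
        return replace(
            self,
            cardiac_amp=self.cardiac_amp * factor,
            resp_amp=self.resp_amp * factor,
            mayer_amp=self.mayer_amp * factor,
            drift_per_min=self.drift_per_min * factor,
            white_sd=self.white_sd * factor,
        )


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the synthetic recording.

    Defaults emulate a walking-like block: 6 repetitions of mean duration
    6.60 s (SD 1.30 s) sampled at 10.27 Hz, with a 0.5 uM evoked HbO2
    peak and HbR at -1/3 of HbO2, delayed by 1 s.
    """

    fs: float = 10.27
    n_reps: int = 6
    duration_mean: float = 6.60
    duration_sd: float = 1.30
    iti_mean: float = 25.0  # rest between task offset and next onset, s
    amplitude_hbo: float = 0.5  # peak evoked HbO2, uM
    hbr_ratio: float = -1.0 / 3.0
    hbr_delay_s: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_channels: int = 2
    seed: int = 0
    condition: str = "task"
    initial_rest_s: float = 15.0
    final_rest_s: float = 20.0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least 2 repetitions")
        if not (self.duration_mean > 2 * self.duration_sd > 0):
            raise ValueError(
                "need duration_mean > 2*duration_sd > 0 to keep durations positive"
            )
        if self.fs <= 2 * self.noise.cardiac_hz:
            raise ValueError("fs must exceed twice the cardiac frequency")


def double_gamma_kernel(t: np.ndarray, peak_s: float = 6.0,
                        undershoot_s: float = 16.0,
                        undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma impulse response, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, peak_s, scale=1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_s, scale=1.0
    )
    return h / h.max()


def draw_durations(p: SimParams, rng: np.random.Generator,
                   n: int | None = None) -> np.ndarray:
    """Truncated-normal task durations: mean +/- 3 SD, floored at 0.5 s."""
    n = p.n_reps if n is None else n
    d = truncnorm.rvs(-3.0, 3.0, loc=p.duration_mean, scale=p.duration_sd,
                      size=n, random_state=rng)
    return np.maximum(d, 0.5)


def _evoked_trace(p: SimParams, time: np.ndarray, onsets: np.ndarray,
                  durations: np.ndarray) -> np.ndarray:
    """Noise-free HbO2 evoked response: kernel (*) boxcar, global peak = amplitude."""
    boxcar = np.zeros_like(time)
    for on, dur in zip(onsets, durations):
        boxcar[(time >= on) & (time < on + dur)] = 1.0
    tk = np.arange(0.0, 32.0, 1.0 / p.fs)
    kernel = double_gamma_kernel(tk)
    conv = np.convolve(boxcar, kernel)[: time.size] / p.fs
    peak = conv.max()
    if peak > 0:
        conv = conv * (p.amplitude_hbo / peak)
    return conv


def generate_recording(p: SimParams) -> Recording:
    """Simulate one continuous recording with stim events for each repetition."""
    rng = np.random.default_rng(p.seed)
    durations = draw_durations(p, rng)
    itis = p.iti_mean * rng.uniform(0.8, 1.2, size=p.n_reps - 1)
    onsets = np.empty(p.n_reps)
    onsets[0] = p.initial_rest_s
    for k in range(1, p.n_reps):
        onsets[k] = onsets[k - 1] + durations[k - 1] + itis[k - 1]

    total = onsets[-1] + durations[-1] + p.final_rest_s
    n = int(np.floor(total * p.fs)) + 1
    time = np.arange(n) / p.fs

    evoked_hbo = _evoked_trace(p, time, onsets, durations)
    delay = int(round(p.hbr_delay_s * p.fs))
    evoked_hbr = p.hbr_ratio * np.concatenate(
        [np.zeros(delay), evoked_hbo[: n - delay]]
    )

    data = np.empty((n, p.n_channels, 3))
    for ci in range(p.n_channels):
        data[:, ci, 0] = evoked_hbo + _noise(p.noise, time, rng)
        data[:, ci, 1] = evoked_hbr + _noise(p.noise.scaled(0.5), time, rng)
        data[:, ci, 2] = data[:, ci, 0] + data[:, ci, 1]

    stims = [
        StimEvent(p.condition, float(on), float(dur))
        for on, dur in zip(onsets, durations)
    ]
    channels = [ChannelInfo(i + 1, i + 1) for i in range(p.n_channels)]
    return Recording(time=time, data=data, chromophores=("HbO2", "HbR", "HbT"),
                     channels=channels, stims=stims, fs=p.fs)


def _noise(np_: NoiseParams, time: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(time)
    for f, a in ((np_.cardiac_hz, np_.cardiac_amp),
                 (np_.resp_hz, np_.resp_amp),
                 (np_.mayer_hz, np_.mayer_amp)):
        phase = rng.uniform(0, 2 * np.pi)
        out += a * np.sin(2 * np.pi * f * time + phase)
    out += np_.drift_per_min * time / 60.0
    if np_.white_sd > 0:
        out += rng.normal(0.0, np_.white_sd, size=time.size)
    elif np_.white_sd == 0:
        rng.normal(0.0, 1.0, size=time.size)  # keep the stream aligned
    return out


def evoked_reference_peak(p: SimParams, config: NormalizationConfig) -> float:
    """Noise-free oracle for amplitude recovery, measured on the raw signal.

    Regenerates the recording with all noise terms off (same seed, so the
    same trial layout) and returns the mean over repetitions of the
    baseline-relative HbO2 peak inside the task+post window — computed
    directly on the continuous trace, with no spline or averaging step.
    """
    clean = generate_recording(replace(p, noise=NoiseParams.zero()))
    hbo = clean.data[:, 0, 0]
    peaks = []
    for s in clean.stims_for(p.condition):
        base = (clean.time >= s.onset - config.deltat_base) & (clean.time < s.onset)
        win = (clean.time >= s.onset) & (
            clean.time <= s.onset + s.duration + config.deltat_post
        )
        peaks.append(hbo[win].max() - hbo[base].mean())
    return float(np.mean(peaks))


def write_snirf_fixture(rec: Recording, path) -> None:
    """Write a Recording as a SNIRF-conformant HDF5 file.

    Output is byte-stable: the same Recording always produces the same
    file (HDF5 object timestamps are disabled).
    """
    with h5py.File(path, "w", track_order=False) as f:
        _ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _ds(meta, "SubjectID", "synthetic")
        _ds(meta, "MeasurementDate", "unknown")
        _ds(meta, "MeasurementTime", "unknown")
        _ds(meta, "LengthUnit", "mm")
        _ds(meta, "TimeUnit", "s")
        _ds(meta, "FrequencyUnit", "Hz")

        n_k = len(rec.chromophores)
        series = rec.data.reshape(rec.n_samples, rec.n_channels * n_k)
        d1 = nirs.create_group("data1")
        _ds(d1, "dataTimeSeries", series)
        _ds(d1, "time", rec.time)
        col = 0
        for ci, ch in enumerate(rec.channels):
            for chrom in rec.chromophores:
                ml = d1.create_group(f"measurementList{col + 1}")
                _ds(ml, "sourceIndex", ch.source_index)
                _ds(ml, "detectorIndex", ch.detector_index)
                _ds(ml, "wavelengthIndex", 1)
                _ds(ml, "dataType", 99999)  # processed
                _ds(ml, "dataTypeLabel", chrom)
                _ds(ml, "dataTypeIndex", 1)
                col += 1

        probe = nirs.create_group("probe")
        n_src = max(c.source_index for c in rec.channels)
        n_det = max(c.detector_index for c in rec.channels)
        _ds(probe, "wavelengths", np.array([760.0, 850.0]))
        _ds(probe, "sourcePos2D", np.zeros((n_src, 2)))
        _ds(probe, "detectorPos2D", np.zeros((n_det, 2)))

        for si, cond in enumerate(rec.conditions()):
            g = nirs.create_group(f"stim{si + 1}")
            _ds(g, "name", cond)
            rows = np.array(
                [[s.onset, s.duration, s.amplitude] for s in rec.stims_for(cond)]
            )
            _ds(g, "data", rows)


def _ds(group: h5py.Group, name: str, value) -> None:
    if isinstance(value, str):
        group.create_dataset(name, data=value, track_times=False)
    elif isinstance(value, (int, np.integer)):
        group.create_dataset(name, data=np.int32(value), track_times=False)
    else:
        group.create_dataset(name, data=np.asarray(value, dtype=float),
                             track_times=False)
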