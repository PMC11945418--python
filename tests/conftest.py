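"""Shared fixtures: small deterministic recordings and hand-built trial sets."""

from __future__ import annotations

import numpy as np
import pytest

from tasknorm import (
    ChannelInfo,
    NoiseParams,
    NormalizationConfig,
    Recording,
    SimParams,
    StimEvent,
    Trial,
    TrialSet,
    generate_recording,
)


@pytest.fixture
def config():
    return NormalizationConfig(deltat_base=2.0, deltat_post=3.0, C=50, version=1)


@pytest.fixture
def walking_params():
    """Walking-like study conditions: 6 self-paced repetitions, 6.60 +/- 1.30 s."""
    return SimParams(seed=0, n_reps=6, duration_mean=6.60, duration_sd=1.30,
                     n_channels=2)


@pytest.fixture
def walking_recording(walking_params):
    return generate_recording(walking_params)


@pytest.fixture
def clean_params(walking_params):
    from dataclasses import replace

    return replace(walking_params, noise=NoiseParams.zero())


def make_trial(duration: float, config: NormalizationConfig, fs: float = 10.27,
               func=None, n_channels: int = 1, n_chroms: int = 1) -> Trial:
    """Build one epoch sampled at fs whose values follow func(t) (default: sin)."""
    span = config.deltat_base + duration + config.deltat_post
    times = np.arange(0.0, span + 1e-9, 1.0 / fs)
    if func is None:
        func = lambda t: np.sin(2 * np.pi * 0.1 * t)
    vals = np.broadcast_to(
        func(times)[:, None, None], (times.size, n_channels, n_chroms)
    ).copy()
    return Trial(times=times, values=vals, onset_s=config.deltat_base,
                 offset_s=config.deltat_base + duration)


def make_trialset(durations, config: NormalizationConfig, fs: float = 10.27,
                  func=None, condition: str = "task") -> TrialSet:
    trials = [make_trial(d, config, fs=fs, func=func) for d in durations]
    return TrialSet(condition=condition, trials=trials, config=config,
                    channel_labels=["S1-D1"], chromophores=("HbO2",))


def make_recording(n_channels: int = 1, fs: float = 10.0, length_s: float = 60.0,
                   stims=None) -> Recording:
    """Small deterministic recording with a slow sinusoid signal."""
    time = np.arange(0.0, length_s, 1.0 / fs)
    vals = np.sin(2 * np.pi * 0.05 * time)
    data = np.broadcast_to(vals[:, None, None], (time.size, n_channels, 1)).copy()
    channels = [ChannelInfo(i + 1, i + 1) for i in range(n_channels)]
    if stims is None:
        stims = [StimEvent("task", 10.0, 8.0), StimEvent("task", 30.0, 10.0)]
    return Recording(time=time, data=data, chromophores=("HbO2",),
                     channels=channels, stims=stims, fs=fs)
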