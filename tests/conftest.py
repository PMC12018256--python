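"""Shared fixtures: small noise-free simulated rounds, processed once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tfo.simulate import SimConfig, generate_truth, synthesize_recording
from tfo.demodulate import process_recording
from tfo.acdc import FhrTrace, extract_acdc
from tfo.bll import default_extinction_table


@pytest.fixture(scope="session")
def eps_table():
    return default_extinction_table()


@pytest.fixture(scope="session")
def clean_round():
    """A short noise-free round processed through the analog front end.

    240 s, two 120-s saturation stages 55 % -> 35 %, no detector or ABG
    noise, so every processing stage can be checked against configuration.
    """
    config = SimConfig(
        round_duration=240.0,
        step_duration=120.0,
        sat_start=55.0,
        sat_end=35.0,
        noise_sd=0.0,
        abg_noise_sd=0.0,
        seed=11,
    )
    truth = generate_truth(config)
    recording = synthesize_recording(config, truth)
    wppg = process_recording(recording)
    return config, truth, recording, wppg


@pytest.fixture(scope="session")
def clean_acdc(clean_round):
    """AC/DC series for every detector/wavelength of the clean round."""
    config, truth, _, wppg = clean_round
    fhr = FhrTrace(t=truth.t, fhr_hz=truth.fhr_bpm / 60.0)
    return {
        (d, lam): extract_acdc(wppg.get(d, lam), wppg.fs, fhr, t0=wppg.t0)
        for d in range(config.n_detectors)
        for lam in (740, 850)
    }


@pytest.fixture(scope="session")
def abg_frame(clean_round):
    _, truth, _, _ = clean_round
    return pd.DataFrame({"t": truth.abg_t, "fsao2": truth.abg_fsao2})
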