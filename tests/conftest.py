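"""Shared fixtures: small synthetic experiments with known ground truth."""
from __future__ import annotations

import numpy as np
import pytest

import zwitterphase as zp
from zwitterphase.synthetic import analytic_alignment_constants

#: The production gaussian-well ground truth (3 kBT at 0.55 nm, width 0.12).
WELL = dict(form="gaussian_well", well_depth=3.0, well_center=0.55, well_width=0.12)


@pytest.fixture(scope="session")
def well_model():
    return zp.AnalyticPMF(**WELL)


@pytest.fixture(scope="session")
def flat_model():
    return zp.AnalyticPMF("flat")


def toy_ladder(n=5, z_min=0.4, z_max=1.6, k_z=100.0, k_r=25_000.0):
    """A small, well-overlapping window ladder for fast WHAM tests."""
    return zp.make_window_ladder(n, z_min, z_max, k_z, k_r)


@pytest.fixture(scope="session")
def toy_well_windows(well_model):
    """5-window biased samples of the gaussian well (2,000 retained each).

    The proposal step matches the in-window width so the chains decorrelate
    quickly at this small sample size.
    """
    return zp.sample_experiment(well_model, toy_ladder(), 2000, burn_in=400,
                                seed=101, step=0.15)


@pytest.fixture(scope="session")
def toy_well_pmf(toy_well_windows):
    hists = zp.build_histograms(toy_well_windows, 0.01)
    return zp.solve_wham(hists, toy_well_windows, ref_window=None)


@pytest.fixture(scope="session")
def conformer_setup(well_model):
    """Two-state dimer frames over the main-well ladder, with oracle F_i."""
    model = zp.two_state_dimer_model(delta_f=1.0)
    ladder = zp.make_window_ladder(6, 0.5, 1.0, 600.0, 25_000.0)
    frames = zp.generate_conformer_frames(model, ladder, 1500, seed=21,
                                          z_pmf=well_model)
    f_i = analytic_alignment_constants(well_model, ladder)
    return frames, f_i, ladder


@pytest.fixture(scope="session")
def ref_window_ladder():
    """Ladder whose samples cover both the well and the 1.75-2.25 nm
    reference window, small enough for repeated experiments."""
    return zp.make_window_ladder(14, 0.2, 2.8, 300.0, 25_000.0)
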