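"""Shared fixtures: expensive synthetic movies are built once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from mtswarm import RunConfig, run_full
from mtswarm.swarm import RenderParams, SwarmParams, brownian_movie, generate_movie

#: Ground-truth speed (μm/s) of the ballistic benchmark movie.
BALLISTIC_SPEED_UM_S = 1.0
#: Ground-truth diffusivity (μm²/s) of the Brownian benchmark movie.
BROWNIAN_D_UM2_S = 0.3


def make_ballistic_movie(seed: int = 11):
    """Non-interacting point-like rods at a single known speed.

    Short rods (≈0.5 μm) keep the orientation-dependent form factor flat at
    the probed wave numbers, so the ensemble ISF is the ideal isotropic
    ballistic J0(q v Δt); rotational diffusion and sticking are off so the
    speed is the only dynamic scale.
    """
    sp = SwarmParams(
        arena=(64.0, 64.0),
        n_filaments=150,
        speed_mean=BALLISTIC_SPEED_UM_S * 60.0,
        speed_sd=0.0,
        length_mean=0.5,
        length_sd=0.01,
        rotational_diffusion=0.0,
        sticking_rate=0.0,
        seed=seed,
    )
    rp = RenderParams(
        pixel_size=0.5, psf_sigma=0.6, frame_interval=0.5, n_frames=45,
        photon_scale=200.0, read_noise=2.0,
    )
    movie, _log = generate_movie(sp, rp, None)
    return movie


def make_brownian_movie(seed: int = 5):
    rp = RenderParams(
        pixel_size=0.5, psf_sigma=0.5, frame_interval=0.5, n_frames=60,
        photon_scale=200.0, read_noise=0.0,
    )
    return brownian_movie(300, BROWNIAN_D_UM2_S, rp, arena=(64.0, 64.0), seed=seed)


@pytest.fixture(scope="session")
def ballistic_movie():
    return make_ballistic_movie()


@pytest.fixture(scope="session")
def brownian_benchmark():
    return make_brownian_movie()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (controller -> movie -> analyses)."""
    outdir = tmp_path_factory.mktemp("default_run")
    manifest = run_full(RunConfig(), outdir)
    return {
        "dir": outdir,
        "manifest": manifest,
        "coloc": pd.read_csv(outdir / "coloc_trace.csv"),
        "gt_summary": pd.read_csv(outdir / "ground_truth_summary.csv"),
        "ddm_blocked": pd.read_csv(outdir / "ddm_trace.csv"),
        "ddm_windows": pd.read_csv(outdir / "ddm_windows.csv"),
        "controller": pd.read_csv(outdir / "controller.csv"),
    }


@pytest.fixture(scope="session")
def sticking_movie():
    """No binding, progressive surface sticking: the single-filament-scale
    relaxation time should grow as filaments immobilize."""
    sp = SwarmParams(n_filaments=60, sticking_rate=0.02, seed=3)
    rp = RenderParams(n_frames=120)
    movie, log = generate_movie(sp, rp, None)
    return movie, log
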