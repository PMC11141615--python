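"""End-to-end orchestration: controller → synthetic movie → analyses.

A single :class:`RunConfig` (YAML-serializable) drives the full in-silico
experiment: the controller ODEs produce the linker/dissociator time
courses, the swarm simulator turns them into a two-channel movie with
ground truth, and the colocalization and DDM analyses quantify the
resulting assembly/disassembly.  One master seed is expanded into the
stochastic stage; rerunning an identical config reproduces every artifact
byte for byte.

Units are fixed package-wide: minutes for time courses, seconds for frame
intervals and relaxation times, μm for lengths, nM for concentrations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .controller import (
    ControllerTrajectory,
    EnzymeConfig,
    build_controller_network,
    simulate,
)
from .coloc import trace as coloc_trace
from .ddm import DEFAULT_BLOCK, DEFAULT_WAVELENGTHS_UM, DEFAULT_WINDOW_LEN, RelaxationTrace, relaxation_trace
from .errors import ConfigurationError, MtswarmError
from .stack import MovieStack
from .swarm import RenderParams, SwarmParams, generate_movie

__all__ = ["RunConfig", "RunManifest", "StageError", "run_full", "analyze_only"]


class StageError(MtswarmError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisParams:
    window: int = DEFAULT_WINDOW_LEN
    block: int = DEFAULT_BLOCK
    wavelengths_um: tuple[float, ...] = DEFAULT_WAVELENGTHS_UM


@dataclass
class RunConfig:
    """Complete configuration of one in-silico experiment."""

    seed: int = 0
    t_end_min: float = 90.0
    controller_species: dict[str, float] = field(default_factory=dict)
    controller_rates: dict[str, float] = field(default_factory=dict)
    enzymes: EnzymeConfig = field(default_factory=EnzymeConfig)
    swarm: SwarmParams = field(default_factory=SwarmParams)
    render: RenderParams = field(default_factory=RenderParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["enzymes"] = dataclasses.asdict(self.enzymes)
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        for key in ("seed", "t_end_min", "controller_species", "controller_rates"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "enzymes" in raw:
            enz = raw.pop("enzymes")
            kwargs["enzymes"] = EnzymeConfig(
                polymerase_activity=enz.get("polymerase_activity", enz.get("polymerase", 1.0)),
                nickase_activity=enz.get("nickase_activity", enz.get("nickase", 1.0)),
                restriction_activity=enz.get("restriction_activity", enz.get("restriction", 1.0)),
            )
        if "swarm" in raw:
            sw = dict(raw.pop("swarm"))
            if "arena" in sw:
                sw["arena"] = tuple(sw["arena"])
            kwargs["swarm"] = SwarmParams(**sw)
        if "render" in raw:
            kwargs["render"] = RenderParams(**raw.pop("render"))
        if "analysis" in raw:
            an = dict(raw.pop("analysis"))
            if "wavelengths_um" in an:
                an["wavelengths_um"] = tuple(an["wavelengths_um"])
            kwargs["analysis"] = AnalysisParams(**an)
        if raw:
            raise ConfigurationError(f"unknown config sections: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """SHA-256 of the canonical config serialization: any numeric change
        (including a default) changes the hash."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, seed=seed, swarm=dataclasses.replace(self.swarm, seed=seed))


@dataclass
class RunManifest:
    """Record of one pipeline run: config identity, stage status, artifacts."""

    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, status: str, paths: list[str] | None = None,
               error: str | None = None) -> None:
        entry: dict[str, Any] = {"status": status, "outputs": paths or []}
        if error:
            entry["error"] = error
        self.stages[stage] = entry

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_full(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute controller → movie → colocalization + DDM, writing artifacts.

    Artifacts in ``outdir``: controller.csv, movie.tif (+ .json sidecar),
    ground_truth.csv, ground_truth_summary.csv, coloc_trace.csv,
    ddm_windows.csv, ddm_trace.csv, manifest.json.  A stage failure writes
    the manifest with a failure marker for that stage and raises
    :class:`StageError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the master seed is authoritative for the stochastic stage
    config = config.with_seed(config.seed)
    manifest = RunManifest(config.config_hash(), __version__, config.seed)
    config.to_yaml(outdir / "config.yaml")

    movie_span_min = (config.render.n_frames - 1) * config.render.frame_interval / 60.0
    t_end = max(config.t_end_min, movie_span_min)

    def _run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            manifest.record(name, "failed", error=str(exc))
            manifest.write(outdir / "manifest.json")
            raise StageError(name, exc) from exc

    def _controller() -> ControllerTrajectory:
        net = build_controller_network(
            enzymes=config.enzymes,
            initials=config.controller_species or None,
            rates=config.controller_rates or None,
        )
        traj = simulate(net, t_end)
        traj.to_csv(outdir / "controller.csv")
        manifest.record("controller", "ok", ["controller.csv"])
        return traj

    traj = _run_stage("controller", _controller)

    def _movie():
        movie, log = generate_movie(config.swarm, config.render, traj)
        movie.to_tiff(
            outdir / "movie.tif",
            extra_metadata={
                "seed": config.seed,
                "swarm_params": dataclasses.asdict(config.swarm),
                "render_params": dataclasses.asdict(config.render),
            },
        )
        log.to_csv(outdir / "ground_truth.csv", outdir / "ground_truth_summary.csv")
        manifest.record(
            "movie", "ok",
            ["movie.tif", "movie.tif.json", "ground_truth.csv", "ground_truth_summary.csv"],
        )
        return movie

    movie = _run_stage("movie", _movie)

    def _coloc():
        df = coloc_trace(movie)
        df.to_csv(outdir / "coloc_trace.csv", index=False, float_format="%.10g")
        manifest.record("coloc", "ok", ["coloc_trace.csv"])
        return df

    _run_stage("coloc", _coloc)

    def _ddm():
        rt = relaxation_trace(
            movie,
            wavelengths_um=config.analysis.wavelengths_um,
            window_len=config.analysis.window,
            block=config.analysis.block,
        )
        rt.per_window.to_csv(outdir / "ddm_windows.csv", index=False, float_format="%.10g")
        rt.blocked.to_csv(outdir / "ddm_trace.csv", index=False, float_format="%.10g")
        manifest.record("ddm", "ok", ["ddm_windows.csv", "ddm_trace.csv"])
        return rt

    _run_stage("ddm", _ddm)

    manifest.write(outdir / "manifest.json")
    return manifest


def analyze_only(
    movie_path: str | Path,
    analysis: AnalysisParams | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> tuple[pd.DataFrame, RelaxationTrace]:
    """Run both analyses on an existing two-channel TIFF recording.

    Calibration comes from the TIFF/JSON metadata unless overridden; a
    movie without calibration raises an error naming the flags to supply.
    """
    analysis = analysis or AnalysisParams()
    movie = MovieStack.from_tiff(
        movie_path, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s
    )
    coloc = coloc_trace(movie)
    rt = relaxation_trace(
        movie,
        wavelengths_um=analysis.wavelengths_um,
        window_len=analysis.window,
        block=analysis.block,
    )
    return coloc, rt
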