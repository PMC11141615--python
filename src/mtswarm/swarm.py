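"""Agent-based synthesis of two-channel gliding-filament movies.

Rigid rods glide at constant speed on a periodic 2-D arena, standing in for
GMPCPP-stabilized microtubules driven by surface kinesins.  Filaments carry
one of two receptor DNAs (green or magenta channel).  A linker concentration
converts cross-channel proximity into pairwise bonds (bundling); a
dissociator concentration breaks bonds (release).  A slow Poisson process
immobilizes filaments, emulating the gradual surface sticking seen in long
motility recordings.

Bundles are connected components of the bond graph: members co-translate
with the component's mean velocity and relax their orientations toward the
component mean.  This is the simplest co-moving representation of
"bundle-like structures" sufficient for exercising the downstream
colocalization and DDM analyses against known ground truth.

Rendering rasterizes each rod as a uniform line (~2 px wide), blurs with an
isotropic Gaussian PSF, and applies Poisson shot noise plus Gaussian read
noise.  A master seed expands into independent substreams for placement,
motion, binding, sticking, and noise, so e.g. regenerating with a different
noise seed leaves trajectories untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .controller import ControllerTrajectory
from .errors import ConfigurationError, RangeError, ValidationError
from .stack import CHANNELS, MovieStack

__all__ = [
    "SwarmParams",
    "RenderParams",
    "SwarmWorld",
    "GroundTruthLog",
    "init_world",
    "step",
    "render_frame",
    "generate_movie",
    "brownian_movie",
]

#: Minimum filament length (μm) at which the length distribution is truncated.
MIN_LENGTH_UM = 0.5


@dataclass(frozen=True)
class SwarmParams:
    """Physical and kinetic parameters of the gliding-filament world.

    Lengths are drawn from a normal distribution (mean 6.2 μm, SD 2.2 μm,
    the measured distribution of the GMPCPP filaments) truncated at
    ``MIN_LENGTH_UM``.  The default speed of 29.4 μm/min (0.49 μm/s) reads
    the reported gliding velocity as 490 nm/s; see the methods note.
    Binding converts linker concentration (nM) into a per-pair bond
    probability ``1 - exp(-k_on_scale * linker * dt)`` for cross-channel
    pairs closer than ``binding_radius``; unbinding uses ``k_off_scale``
    with the dissociator concentration, and free filaments stick at
    ``sticking_rate``.
    """

    arena: tuple[float, float] = (64.0, 64.0)  # μm, periodic
    n_filaments: int = 80                      # per channel
    speed_mean: float = 29.4                   # μm/min
    speed_sd: float = 1.2                      # μm/min
    length_mean: float = 6.2                   # μm
    length_sd: float = 2.2                     # μm
    rotational_diffusion: float = 0.02         # rad²/min
    binding_radius: float = 0.5                # μm
    k_on_scale: float = 0.004                  # per-(nM·min)
    k_off_scale: float = 0.004                 # per-(nM·min)
    sticking_rate: float = 0.008               # per-min
    alignment_rate: float = 2.0                # per-min, in-bundle orientation relaxation
    seed: int = 0

    def __post_init__(self) -> None:
        positives = (
            "speed_mean", "length_mean", "length_sd", "binding_radius",
            "k_on_scale", "k_off_scale", "alignment_rate",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("speed_sd", "rotational_diffusion", "sticking_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValidationError("arena dimensions must be > 0")
        if self.n_filaments < 0:
            raise ValidationError("n_filaments must be >= 0")


@dataclass(frozen=True)
class RenderParams:
    """Optics and camera model of the synthetic microscope."""

    pixel_size: float = 0.5     # μm/px
    psf_sigma: float = 0.6      # μm
    frame_interval: float = 20.0  # s
    n_frames: int = 180
    photon_scale: float = 40.0  # expected photons per μm of filament per pixel row
    read_noise: float = 2.0     # counts RMS

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")


class SwarmWorld:
    """Mutable state of all filaments plus the pairwise bond set."""

    def __init__(self, params: SwarmParams, x, y, theta, length, speed, channel):
        self.params = params
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.length = np.asarray(length, dtype=float)
        self.speed = np.asarray(speed, dtype=float)
        self.channel = np.asarray(channel, dtype=np.int64)  # 0 green, 1 magenta
        self.stuck = np.zeros(self.x.size, dtype=bool)
        self.bonds: set[tuple[int, int]] = set()
        self.time_min: float = 0.0
        # independent RNG substreams
        ss = np.random.SeedSequence(params.seed)
        s_place, s_motion, s_bind, s_stick, s_noise = ss.spawn(5)
        self.rng_motion = np.random.default_rng(s_motion)
        self.rng_bind = np.random.default_rng(s_bind)
        self.rng_stick = np.random.default_rng(s_stick)
        self.rng_noise = np.random.default_rng(s_noise)

    @property
    def n(self) -> int:
        return self.x.size

    def bundle_ids(self) -> np.ndarray:
        """Connected-component label per filament; -1 for unbundled."""
        labels = np.full(self.n, -1, dtype=np.int64)
        if not self.bonds:
            return labels
        adj: dict[int, list[int]] = {}
        for i, j in self.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        next_label = 0
        for start in sorted(adj):
            if labels[start] != -1:
                continue
            stack = [start]
            labels[start] = next_label
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if labels[v] == -1:
                        labels[v] = next_label
                        stack.append(v)
            next_label += 1
        return labels


def init_world(params: SwarmParams) -> SwarmWorld:
    """Place ``2 * n_filaments`` rods uniformly at random on the arena.

    Orientations are uniform on [0, 2π); lengths are truncated-normal;
    speeds are normal clipped at 0.  Fully reproducible from ``params.seed``.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(5)[0])  # placement substream
    n = 2 * params.n_filaments
    w, h = params.arena
    x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    length = rng.normal(params.length_mean, params.length_sd, n)
    # redraw below the truncation point rather than clipping, to keep the
    # sample mean near the nominal value
    bad = length < MIN_LENGTH_UM
    guard = 0
    while bad.any():
        length[bad] = rng.normal(params.length_mean, params.length_sd, bad.sum())
        bad = length < MIN_LENGTH_UM
        guard += 1
        if guard > 1000:
            raise ConfigurationError(
                "length distribution is almost entirely below the 0.5 μm cutoff"
            )
    if params.n_filaments > 0 and length.sum() * 3.0 > 4 * w * h:
        raise ConfigurationError("filament density too high for the arena")
    speed = np.clip(rng.normal(params.speed_mean, params.speed_sd, n), 0, None)
    channel = np.repeat([0, 1], params.n_filaments)
    return SwarmWorld(params, x, y, theta, length, speed, channel)


def _wrap_delta(d: np.ndarray, span: float) -> np.ndarray:
    """Nearest-image displacement on a periodic axis."""
    return d - span * np.round(d / span)


def _segment_min_dist(dx, dy, th1, L1, th2, L2):
    """Minimum distance between 2-D segments centred at (0,0) and (dx,dy).

    Vectorized closest-point computation with clamping to the segment
    extents (robust for near-parallel pairs).
    """
    u1x, u1y = np.cos(th1), np.sin(th1)
    u2x, u2y = np.cos(th2), np.sin(th2)
    h1, h2 = L1 / 2.0, L2 / 2.0
    b = u1x * u2x + u1y * u2y
    d = u1x * dx + u1y * dy
    e = u2x * dx + u2y * dy
    denom = 1.0 - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-12, (d - b * e) / np.maximum(denom, 1e-12), 0.0)
    s = np.clip(s, -h1, h1)
    t = np.clip(s * b - e, -h2, h2)
    s = np.clip(t * b + d, -h1, h1)
    t = np.clip(s * b - e, -h2, h2)
    px = dx + t * u2x - s * u1x
    py = dy + t * u2y - s * u1y
    return np.hypot(px, py)


def step(
    world: SwarmWorld,
    dt: float,
    linker_nM: float,
    dissociator_nM: float,
) -> SwarmWorld:
    """Advance the world in place by ``dt`` minutes and return it.

    Order of sub-steps: motion (free gliding + bundle co-translation and
    orientation relaxation), periodic wrap, cross-channel binding, bond
    breaking, sticking.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if linker_nM < 0 or dissociator_nM < 0:
        raise ValidationError("concentrations must be >= 0")
    p = world.params
    w, h = p.arena
    n = world.n
    if n == 0:
        world.time_min += dt
        return world

    labels = world.bundle_ids()
    mobile = ~world.stuck
    vx = np.where(mobile, world.speed * np.cos(world.theta), 0.0)
    vy = np.where(mobile, world.speed * np.sin(world.theta), 0.0)

    free = labels < 0
    world.x[free] += vx[free] * dt
    world.y[free] += vy[free] * dt
    kick = world.rng_motion.standard_normal(n) * np.sqrt(2 * p.rotational_diffusion * dt)
    world.theta[free & mobile] += kick[free & mobile]

    for lab in range(labels.max() + 1 if labels.size else 0):
        members = np.flatnonzero(labels == lab)
        # stuck members anchor the bundle: they contribute zero velocity
        bvx = vx[members].mean()
        bvy = vy[members].mean()
        world.x[members] += bvx * dt
        world.y[members] += bvy * dt
        # nematic orientation relaxation toward the bundle mean axis
        mean_axis = 0.5 * np.arctan2(
            np.sin(2 * world.theta[members]).sum(), np.cos(2 * world.theta[members]).sum()
        )
        mism = world.theta[members] - mean_axis
        mism = np.arctan2(np.sin(2 * mism), np.cos(2 * mism)) / 2.0
        relax = -np.clip(p.alignment_rate * dt, 0, 1) * mism
        mobile_members = members[mobile[members]]
        world.theta[mobile_members] += relax[mobile[members]]

    world.x %= w
    world.y %= h

    # --- binding: cross-channel proximity + linker-driven probability
    if linker_nM > 0:
        green = np.flatnonzero(world.channel == 0)
        magenta = np.flatnonzero(world.channel == 1)
        if green.size and magenta.size:
            gi = np.repeat(green, magenta.size)
            mj = np.tile(magenta, green.size)
            dx = _wrap_delta(world.x[mj] - world.x[gi], w)
            dy = _wrap_delta(world.y[mj] - world.y[gi], h)
            # cheap prefilter on centroid distance before exact segment distance
            reach = (world.length[gi] + world.length[mj]) / 2 + p.binding_radius
            near = dx * dx + dy * dy <= reach * reach
            gi, mj, dx, dy = gi[near], mj[near], dx[near], dy[near]
            dist = _segment_min_dist(
                dx, dy, world.theta[gi], world.length[gi], world.theta[mj], world.length[mj]
            )
            close = dist < p.binding_radius
            gi, mj = gi[close], mj[close]
            p_bind = 1.0 - np.exp(-p.k_on_scale * linker_nM * dt)
            roll = world.rng_bind.random(gi.size)
            for a, b_ in zip(gi[roll < p_bind], mj[roll < p_bind]):
                pair = (int(min(a, b_)), int(max(a, b_)))
                world.bonds.add(pair)

    # --- breaking: dissociator-driven, independent per bond
    if dissociator_nM > 0 and world.bonds:
        p_break = 1.0 - np.exp(-p.k_off_scale * dissociator_nM * dt)
        bonds = sorted(world.bonds)
        roll = world.rng_bind.random(len(bonds))
        world.bonds = {b_ for b_, r in zip(bonds, roll) if r >= p_break}

    # --- sticking: free (unbundled), still-mobile filaments only
    if p.sticking_rate > 0:
        labels = world.bundle_ids()
        candidates = (labels < 0) & ~world.stuck
        p_stick = 1.0 - np.exp(-p.sticking_rate * dt)
        roll = world.rng_stick.random(n)
        world.stuck |= candidates & (roll < p_stick)

    world.time_min += dt
    return world


def _splat_bilinear(canvas: np.ndarray, px: np.ndarray, py: np.ndarray,
                    weights: np.ndarray, pixel_size: float) -> None:
    """Deposit point masses with bilinear (triangle-kernel) weights.

    Bilinear splatting keeps the exact sub-pixel phase of every point (the
    raster equals a fixed triangle kernel centred at the true position), so
    rendering adds no spurious frame-to-frame jitter to the dynamics —
    nearest-pixel snapping would bias DDM relaxation rates upward.
    """
    H, W = canvas.shape
    fx = px / pixel_size - 0.5
    fy = py / pixel_size - 0.5
    c0 = np.floor(fx).astype(int)
    r0 = np.floor(fy).astype(int)
    wx = fx - c0
    wy = fy - r0
    for dr, dc, wgt in (
        (0, 0, (1 - wy) * (1 - wx)),
        (0, 1, (1 - wy) * wx),
        (1, 0, wy * (1 - wx)),
        (1, 1, wy * wx),
    ):
        np.add.at(canvas, ((r0 + dr) % H, (c0 + dc) % W), weights * wgt)


def _deposit(world: SwarmWorld, rp: RenderParams, channel: int) -> np.ndarray:
    """Unblurred line-raster of one channel (intensity ∝ filament length)."""
    w_um, h_um = world.params.arena
    W = int(round(w_um / rp.pixel_size))
    H = int(round(h_um / rp.pixel_size))
    canvas = np.zeros((H, W))
    idx = np.flatnonzero(world.channel == channel)
    ds = 0.25 * rp.pixel_size  # sub-pixel sampling step along the rod
    half_width = 0.5 * rp.pixel_size  # ±: total raster width ~2 px
    for i in idx:
        L = world.length[i]
        npts = max(2, int(np.ceil(L / ds)))
        s = (np.linspace(0, 1, npts) - 0.5) * L
        ux, uy = np.cos(world.theta[i]), np.sin(world.theta[i])
        for off in (-half_width / 2, half_width / 2):
            px = (world.x[i] + s * ux - off * uy) % w_um
            py = (world.y[i] + s * uy + off * ux) % h_um
            _splat_bilinear(
                canvas, px, py, np.full(npts, L / (2 * npts)), rp.pixel_size
            )
    return canvas


def render_frame(
    world: SwarmWorld, rp: RenderParams, noise: bool = True
) -> np.ndarray:
    """Render both channels of the current state as a (2, H, W) image.

    With ``noise=False`` the noiseless blurred intensity field is returned
    (floating point, mass-conserving); with ``noise=True`` Poisson shot
    noise and Gaussian read noise are applied and the result is quantized
    to non-negative integer counts (16-bit camera model).
    """
    frames = []
    sigma_px = rp.psf_sigma / rp.pixel_size
    for c in range(len(CHANNELS)):
        base = _deposit(world, rp, c)
        base = gaussian_filter(base, sigma_px, mode="wrap") * rp.photon_scale
        if noise:
            img = world.rng_noise.poisson(base).astype(np.float64)
            img += np.round(world.rng_noise.normal(0.0, rp.read_noise, img.shape))
            img = np.clip(img, 0, np.iinfo(np.uint16).max)
        else:
            img = base
        frames.append(img)
    return np.stack(frames)


class GroundTruthLog:
    """Per-frame ground truth of the generated movie.

    ``filaments`` has one row per filament per frame (frame, filament_id,
    channel, x, y, orientation, length, bundle_id, stuck); ``summary`` one
    row per frame (frame, time_min, linker_nM, dissociator_nM, n_bonds,
    bound_fraction, stuck_fraction, contact_fraction).  The contact fraction
    is the Jaccard overlap of the two channels' unblurred occupancy masks —
    the geometric quantity the colocalization statistic estimates.
    """

    def __init__(self, filaments: pd.DataFrame, summary: pd.DataFrame):
        self.filaments = filaments
        self.summary = summary

    def to_csv(self, filament_path, summary_path) -> None:
        self.filaments.to_csv(filament_path, index=False, float_format="%.6g")
        self.summary.to_csv(summary_path, index=False, float_format="%.6g")


def _contact_fraction(world: SwarmWorld, rp: RenderParams) -> float:
    g = _deposit(world, rp, 0) > 0
    m = _deposit(world, rp, 1) > 0
    union = np.count_nonzero(g | m)
    if union == 0:
        return 0.0
    return np.count_nonzero(g & m) / union


def generate_movie(
    params: SwarmParams,
    rp: RenderParams,
    controller_traj: ControllerTrajectory | None = None,
) -> tuple[MovieStack, GroundTruthLog]:
    """Step the world at the frame interval and render every frame.

    Linker and dissociator concentrations are sampled from
    ``controller_traj`` by linear interpolation at each frame time; ``None``
    means both are identically zero (non-interacting filaments).  The
    trajectory must cover the whole movie span.
    """
    dt_min = rp.frame_interval / 60.0
    span = (rp.n_frames - 1) * dt_min
    if controller_traj is not None and controller_traj.times[-1] < span - 1e-9:
        raise RangeError(
            f"controller trajectory ends at {controller_traj.times[-1]:.3g} min "
            f"but the movie spans {span:.3g} min"
        )

    world = init_world(params)
    frames = []
    fil_rows = []
    sum_rows = []
    for k in range(rp.n_frames):
        t = k * dt_min
        frames.append(render_frame(world, rp, noise=True))
        labels = world.bundle_ids()
        if controller_traj is not None:
            linker = float(controller_traj.interpolate("linker", np.array([t]))[0])
            diss = float(controller_traj.interpolate("dissociator", np.array([t]))[0])
        else:
            linker = diss = 0.0
        fil_rows.append(
            pd.DataFrame(
                {
                    "frame": k,
                    "filament_id": np.arange(world.n),
                    "channel": np.array(CHANNELS)[world.channel],
                    "x": world.x,
                    "y": world.y,
                    "orientation": world.theta,
                    "length": world.length,
                    "bundle_id": labels,
                    "stuck": world.stuck,
                }
            )
        )
        sum_rows.append(
            {
                "frame": k,
                "time_min": t,
                "linker_nM": linker,
                "dissociator_nM": diss,
                "n_bonds": len(world.bonds),
                "bound_fraction": float(np.mean(labels >= 0)) if world.n else 0.0,
                "stuck_fraction": float(world.stuck.mean()) if world.n else 0.0,
                "contact_fraction": _contact_fraction(world, rp),
            }
        )
        if k < rp.n_frames - 1:
            step(world, dt_min, linker, diss)

    stack = MovieStack(
        np.stack(frames), pixel_size_um=rp.pixel_size, frame_interval_s=rp.frame_interval
    )
    log = GroundTruthLog(
        pd.concat(fil_rows, ignore_index=True), pd.DataFrame(sum_rows)
    )
    return stack, log


def brownian_movie(
    n_particles: int,
    diffusivity_um2_s: float,
    rp: RenderParams,
    arena: tuple[float, float] = (64.0, 64.0),
    spot_sigma_um: float = 0.5,
    seed: int = 0,
) -> MovieStack:
    """A two-channel movie of independent Brownian point emitters.

    A calibration field with a known intermediate scattering function
    ``exp(-D q² Δt)``, used to benchmark the DDM pipeline.  Each channel
    holds an independent particle set; no noise beyond Poisson/rounding is
    applied (read noise 0 keeps the spectral noise floor minimal).
    """
    rng = np.random.default_rng(seed)
    w, h = arena
    W = int(round(w / rp.pixel_size))
    H = int(round(h / rp.pixel_size))
    sigma_px = spot_sigma_um / rp.pixel_size
    step_sd = np.sqrt(2 * diffusivity_um2_s * rp.frame_interval)
    chans = []
    for _c in range(len(CHANNELS)):
        x = rng.uniform(0, w, n_particles)
        y = rng.uniform(0, h, n_particles)
        frames = np.zeros((rp.n_frames, H, W))
        for k in range(rp.n_frames):
            canvas = np.zeros((H, W))
            _splat_bilinear(canvas, x, y, np.ones(n_particles), rp.pixel_size)
            canvas = gaussian_filter(canvas, sigma_px, mode="wrap") * rp.photon_scale
            frames[k] = rng.poisson(canvas)
            x = (x + rng.normal(0, step_sd, n_particles)) % w
            y = (y + rng.normal(0, step_sd, n_particles)) % h
        chans.append(frames)
    return MovieStack(
        np.stack(chans, axis=1), pixel_size_um=rp.pixel_size, frame_interval_s=rp.frame_interval
    )
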