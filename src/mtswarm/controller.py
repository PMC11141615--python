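"""Deterministic kinetics of the DNA strand-displacement controller.

The controller is a three-step isothermal cascade built from three DNA
complexes (Template, Converter, Transducer) and three enzymes (polymerase,
nickase, restriction enzyme).  Step 1: an elongation/nick cycle on the
Template amplifies a short *signal* strand, which strips the *linker*
(the assembly signal) off the Converter.  Step 2: the same signal, reacting
more slowly with the Transducer, releases an *updater* strand that shuts
the Template down.  Step 3: the shut-down Template·updater complex is cut
by the restriction enzyme, turning it into a template for a second
amplification cycle that produces the *dissociator* (the disassembly
signal), which inactivates the linker wherever it is — free, bound to one
receptor, or bridging both.

The multi-enzyme cycles are lumped into single mass-action pseudo-reactions;
the cascade's topology and causal ordering are preserved with the fewest
free parameters.  Units are nM and minutes throughout.  Enzyme "activity" is a
dimensionless multiplier on the lumped rate of the reactions that enzyme
gates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, RangeError, ValidationError

__all__ = [
    "Species",
    "Reaction",
    "EnzymeConfig",
    "ReactionNetwork",
    "ControllerTrajectory",
    "PeakResult",
    "DEFAULT_RATES",
    "DEFAULT_INITIALS",
    "REACTION_KINDS",
    "build_controller_network",
    "simulate",
    "gel_readout",
    "peak_time",
]

#: Reaction kinds admitted by the cascade and the enzyme activities gating them.
REACTION_KINDS = (
    "amplification",
    "conversion",
    "transduction",
    "update",
    "restriction",
    "bridging",
    "removal",
)

#: Rate-table keys and the reaction kind each one parameterizes.
RATE_KEYS = {
    "k_amp": "amplification",
    "k_conv": "conversion",
    "k_trans": "transduction",
    "k_upd": "update",
    "k_cut": "restriction",
    "k_damp": "amplification",
    "k_bridge": "bridging",
    "k_rem": "removal",
}

def _load_defaults() -> tuple[dict[str, float], dict[str, float]]:
    from importlib.resources import files

    import yaml

    raw = yaml.safe_load(files("mtswarm.data").joinpath("controller_defaults.yaml").read_text())
    return dict(raw["rates"]), dict(raw["species"])


# Calibrated defaults (nM, min) from the version-controlled config file.
# They are a documented fit, not a derivation: with all enzyme activities at
# 1 the free-linker pulse peaks near 15 min and has decayed below 5% of its
# peak by ~60 min, and with the restriction enzyme disabled the linker
# plateaus instead of decaying.
DEFAULT_RATES, DEFAULT_INITIALS = _load_defaults()

#: Declared species order of the full cascade (17 species).
SPECIES_ORDER = (
    "template",
    "converter",
    "transducer",
    "receptor1",
    "receptor2",
    "signal",
    "linker",
    "updater",
    "dissociator",
    "template_updater",
    "template_cut",
    "converter_waste",
    "transducer_waste",
    "linker_r1",
    "linker_r2",
    "linker_r1_r2",
    "linker_waste",
)

#: Species whose concentration contains one Template strand.
TEMPLATE_POOL = ("template", "template_updater", "template_cut")

#: Species whose concentration contains one linker strand (Converter-bound,
#: free, receptor-complexed, or inactivated waste).
LINKER_POOL = ("converter", "linker", "linker_r1", "linker_r2", "linker_r1_r2", "linker_waste")


@dataclass(frozen=True)
class Species:
    """A named chemical species with its initial concentration in nM."""

    name: str
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValidationError(
                f"initial concentration of {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactants`` / ``products`` are sequences of ``(species_name, stoichiometry)``
    with positive integer stoichiometries.  ``rate_constant`` is per-min for
    unimolecular steps and per-(nM·min) for bimolecular ones.  ``label``
    identifies the cascade step (R1 … R8) the reaction belongs to; symmetric
    receptor-order variants share a label.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ConfigurationError(f"unknown reaction kind {self.kind!r}")
        if self.rate_constant < 0:
            raise ValidationError(f"rate constant of {self.label or self.kind} must be >= 0")
        for name, stoich in (*self.reactants, *self.products):
            if int(stoich) != stoich or stoich <= 0:
                raise ValidationError(
                    f"stoichiometry of {name!r} must be a positive integer, got {stoich}"
                )


@dataclass(frozen=True)
class EnzymeConfig:
    """Dimensionless activity multipliers for the three enzymes.

    An activity of 1 is the calibrated reference; 0 disables every reaction
    the enzyme gates.  ``restriction_activity`` is the programmability knob:
    lowering it delays the disassembly phase.
    """

    polymerase_activity: float = 1.0
    nickase_activity: float = 1.0
    restriction_activity: float = 1.0

    def __post_init__(self) -> None:
        for fname in ("polymerase_activity", "nickase_activity", "restriction_activity"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{fname} must be >= 0")


class ReactionNetwork:
    """An immutable mass-action network: species order, initials, reactions."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique within a network")
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.names: tuple[str, ...] = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}
        n_sp, n_rx = len(species), len(reactions)
        # reactant-order and net-change matrices for mass-action propensities
        self.order = np.zeros((n_rx, n_sp), dtype=np.int64)
        self.net = np.zeros((n_rx, n_sp), dtype=np.int64)
        for j, rx in enumerate(reactions):
            for name, stoich in rx.reactants:
                i = self._require(name)
                self.order[j, i] += stoich
                self.net[j, i] -= stoich
            for name, stoich in rx.products:
                self.net[j, self._require(name)] += stoich
        self.rate_constants = np.array([rx.rate_constant for rx in reactions])

    def _require(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"reaction references unknown species {name!r}") from None

    def index(self, name: str) -> int:
        return self._require(name)

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def propensities(self, conc: np.ndarray) -> np.ndarray:
        """Mass-action rates (nM/min) of every reaction at concentrations ``conc``."""
        c = np.clip(conc, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self.rate_constants * np.prod(
                np.power(c[None, :], self.order), axis=1
            )
        return rates

    def rhs(self, _t: float, conc: np.ndarray) -> np.ndarray:
        return self.propensities(conc) @ self.net


class PeakResult(NamedTuple):
    """Location of a series' global maximum.  ``no_peak`` flags a series
    with no strictly positive excursion (constant or all-zero)."""

    time: float
    no_peak: bool


@dataclass
class ControllerTrajectory:
    """Concentration time courses on a strictly increasing minute grid."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_species, n_times), nM
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory time grid must be strictly increasing")
        if self.concentrations.shape != (len(self.names), len(self.times)):
            raise ValidationError("concentration matrix must be species x time")

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[self.names.index(name)]

    def pool(self, members: Iterable[str]) -> np.ndarray:
        """Summed concentration of a conserved strand pool."""
        return sum(self.species(m) for m in members)

    def interpolate(self, name: str, at: np.ndarray) -> np.ndarray:
        at = np.asarray(at, dtype=float)
        if np.any(at < self.times[0]) or np.any(at > self.times[-1]):
            raise RangeError(
                f"requested times outside trajectory range "
                f"[{self.times[0]}, {self.times[-1]}] min"
            )
        return np.interp(at, self.times, self.species(name))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations.T, columns=list(self.names))
        df.insert(0, "time_min", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _validate_rates(rates: dict[str, float]) -> dict[str, float]:
    merged = dict(DEFAULT_RATES)
    for key, value in rates.items():
        if key not in RATE_KEYS:
            raise ConfigurationError(f"unknown rate-table entry {key!r}")
        if value < 0:
            raise ValidationError(f"rate {key} must be >= 0, got {value}")
        merged[key] = float(value)
    return merged


def build_controller_network(
    enzymes: EnzymeConfig | None = None,
    initials: Sequence[Species] | dict[str, float] | None = None,
    rates: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Assemble the fixed three-step cascade topology as lumped reactions.

    ``initials`` may override starting concentrations by name; species of the
    cascade that are not mentioned start at 0 nM.  ``rates`` may override any
    subset of :data:`DEFAULT_RATES`.  Enzyme activities multiply the rates of
    the reactions each enzyme gates (polymerase x nickase on both
    amplification cycles, restriction on the Template cut).
    """
    enzymes = enzymes or EnzymeConfig()
    k = _validate_rates(rates or {})

    overrides: dict[str, float] = dict(DEFAULT_INITIALS)
    if initials is not None:
        if isinstance(initials, dict):
            items = initials.items()
        else:
            items = ((s.name, s.initial_concentration) for s in initials)
        overrides = {}
        for name, c0 in items:
            if name not in SPECIES_ORDER:
                raise ConfigurationError(f"unknown species {name!r} in initials")
            overrides[name] = float(c0)

    species = [Species(n, overrides.get(n, 0.0)) for n in SPECIES_ORDER]

    amp = enzymes.polymerase_activity * enzymes.nickase_activity
    cut = enzymes.restriction_activity

    def rx(reactants, products, rate, kind, label):
        return Reaction(tuple(reactants), tuple(products), rate, kind, label)

    reactions = [
        # Step 1: signal amplification and linker release
        rx([("template", 1)], [("template", 1), ("signal", 1)],
           k["k_amp"] * amp, "amplification", "R1"),
        rx([("signal", 1), ("converter", 1)], [("linker", 1), ("converter_waste", 1)],
           k["k_conv"], "conversion", "R2"),
        # Step 2: slower transduction and Template shutdown
        rx([("signal", 1), ("transducer", 1)], [("updater", 1), ("transducer_waste", 1)],
           k["k_trans"], "transduction", "R3"),
        rx([("updater", 1), ("template", 1)], [("template_updater", 1)],
           k["k_upd"], "update", "R4"),
        # Step 3: restriction cut and dissociator amplification
        rx([("template_updater", 1)], [("template_cut", 1)],
           k["k_cut"] * cut, "restriction", "R5"),
        rx([("template_cut", 1)], [("template_cut", 1), ("dissociator", 1)],
           k["k_damp"] * amp, "amplification", "R6"),
        # Receptor bridging, both association orders
        rx([("linker", 1), ("receptor1", 1)], [("linker_r1", 1)],
           k["k_bridge"], "bridging", "R7a"),
        rx([("linker", 1), ("receptor2", 1)], [("linker_r2", 1)],
           k["k_bridge"], "bridging", "R7a"),
        rx([("linker_r1", 1), ("receptor2", 1)], [("linker_r1_r2", 1)],
           k["k_bridge"], "bridging", "R7b"),
        rx([("linker_r2", 1), ("receptor1", 1)], [("linker_r1_r2", 1)],
           k["k_bridge"], "bridging", "R7b"),
        # Dissociator strips the linker from every linker-containing species
        rx([("dissociator", 1), ("linker", 1)], [("linker_waste", 1)],
           k["k_rem"], "removal", "R8"),
        rx([("dissociator", 1), ("linker_r1", 1)], [("linker_waste", 1), ("receptor1", 1)],
           k["k_rem"], "removal", "R8"),
        rx([("dissociator", 1), ("linker_r2", 1)], [("linker_waste", 1), ("receptor2", 1)],
           k["k_rem"], "removal", "R8"),
        rx([("dissociator", 1), ("linker_r1_r2", 1)],
           [("linker_waste", 1), ("receptor1", 1), ("receptor2", 1)],
           k["k_rem"], "removal", "R8"),
    ]
    return ReactionNetwork(species, reactions)


def simulate(
    network: ReactionNetwork,
    t_end: float,
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ControllerTrajectory:
    """Integrate the mass-action ODEs on ``output_grid`` (default: 0.1-min grid).

    Uses a stiff-capable integrator (LSODA).  Concentrations are checked
    against negativity beyond solver tolerance and conservation of the
    Template- and linker-strand pools within 0.1%.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, int(round(t_end / 0.1)) + 1)
    output_grid = np.asarray(output_grid, dtype=float)
    if output_grid[0] < 0 or output_grid[-1] > t_end:
        raise ValidationError("output grid must lie within [0, t_end]")

    y0 = network.initial_state
    sol = solve_ivp(
        network.rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=output_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    conc = sol.y
    neg_tol = 100 * atol + 1e-9
    if conc.min() < -neg_tol:
        raise IntegrationError(
            f"negative concentration beyond tolerance: min={conc.min():.3g} nM"
        )
    conc = np.clip(conc, 0.0, None)
    traj = ControllerTrajectory(sol.t, conc, network.names)

    for pool, label in ((TEMPLATE_POOL, "template"), (LINKER_POOL, "linker")):
        total = traj.pool(pool)
        if total[0] > 0:
            drift = np.max(np.abs(total - total[0])) / total[0]
            if drift > 1e-3:
                raise IntegrationError(
                    f"{label}-strand conservation violated: relative drift {drift:.2e}"
                )
    return traj


def gel_readout(traj: ControllerTrajectory, times: Sequence[float]) -> pd.DataFrame:
    """Emulate the gel quantification: linker, inactivated linker waste
    (linker + elongated dissociator), and the full receptor bridge, linearly
    interpolated at the requested times."""
    times = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "time_min": times,
            "linker": traj.interpolate("linker", times),
            "linker_waste": traj.interpolate("linker_waste", times),
            "linker_r1_r2": traj.interpolate("linker_r1_r2", times),
        }
    )


def peak_time(times: Sequence[float], values: Sequence[float]) -> PeakResult:
    """Time of the global maximum of a series; ties break toward the earliest
    time.  A series with no strictly positive range (constant, or all equal)
    returns time 0 with the ``no_peak`` flag set."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or values.size != times.size:
        raise ValidationError("series must be non-empty and aligned with its time grid")
    if np.ptp(values) == 0:
        return PeakResult(0.0, True)
    return PeakResult(float(times[int(np.argmax(values))]), False)
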