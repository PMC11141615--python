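"""Exact stochastic simulation of a :class:`~mtswarm.controller.ReactionNetwork`.

Direct-method (Gillespie) sampling at finite copy number.  This is a
validation tool for the deterministic ODE engine, not an alternative
production engine: at small reaction volumes the trajectory means should
agree with the mass-action solution to within sampling error, which is what
the test suite checks.

Concentrations (nM) are mapped to copy numbers through ``volume``, expressed
as molecules per nM; a bimolecular rate constant k (per nM per min) becomes
a stochastic rate k/volume (per pair per min).

Uses numba for the inner event loop when it is importable; falls back to the
identical pure-Python loop otherwise.
"""

from __future__ import annotations

import numpy as np

from .controller import ReactionNetwork

__all__ = ["gillespie_checkpoint_stats"]


def _compile_core():
    """Return a batched SSA core, numba-jitted when available."""
    try:
        import numba
    except ImportError:  # pragma: no cover - numba present in supported envs
        numba = None

    def core(order, net, crates, n0, checkpoints, n_runs, seed):
        n_sp = order.shape[1]
        acc_sum = np.zeros((len(checkpoints), n_sp))
        acc_sq = np.zeros((len(checkpoints), n_sp))
        np.random.seed(seed)
        for _run in range(n_runs):
            n = n0.astype(np.float64)
            t = 0.0
            ic = 0
            out = np.zeros((len(checkpoints), n_sp))
            n_rx = order.shape[0]
            while ic < len(checkpoints):
                a0 = 0.0
                a = np.zeros(n_rx)
                for j in range(n_rx):
                    aj = crates[j]
                    for i in range(n_sp):
                        for m in range(order[j, i]):
                            aj *= n[i] - m
                    if aj < 0.0:
                        aj = 0.0
                    a[j] = aj
                    a0 += aj
                if a0 <= 0.0:
                    while ic < len(checkpoints):
                        out[ic] = n
                        ic += 1
                    break
                t_next = t - np.log(np.random.random()) / a0
                while ic < len(checkpoints) and checkpoints[ic] < t_next:
                    out[ic] = n
                    ic += 1
                t = t_next
                r = np.random.random() * a0
                acc = 0.0
                jsel = n_rx - 1
                for j in range(n_rx):
                    acc += a[j]
                    if acc >= r:
                        jsel = j
                        break
                for i in range(n_sp):
                    n[i] += net[jsel, i]
            acc_sum += out
            acc_sq += out * out
        return acc_sum, acc_sq

    if numba is not None:
        core = numba.njit(core, cache=False)
    return core


_CORE = None


def gillespie_checkpoint_stats(
    network: ReactionNetwork,
    checkpoints: np.ndarray,
    n_runs: int = 1000,
    volume: float = 400.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of species concentrations at ``checkpoints``.

    Parameters
    ----------
    checkpoints:
        Strictly increasing times (min) at which the state is recorded.
    n_runs:
        Number of independent realizations.
    volume:
        Molecules per nM; initial copy numbers are rounded from
        concentration x volume.
    seed:
        Seed for the event-loop RNG (kept below 2**31).

    Returns
    -------
    (means, sems):
        Arrays of shape ``(n_checkpoints, n_species)`` in nM.
    """
    global _CORE
    if _CORE is None:
        _CORE = _compile_core()

    checkpoints = np.asarray(checkpoints, dtype=np.float64)
    order = network.order.astype(np.int64)
    net = network.net.astype(np.float64)
    total_order = order.sum(axis=1)
    crates = network.rate_constants * volume ** (1.0 - total_order)
    n0 = np.round(network.initial_state * volume)

    acc_sum, acc_sq = _CORE(
        order, net, crates.astype(np.float64), n0, checkpoints, int(n_runs),
        int(seed) % (2**31 - 1),
    )
    means_counts = acc_sum / n_runs
    var_counts = np.maximum(acc_sq / n_runs - means_counts**2, 0.0) * n_runs / max(n_runs - 1, 1)
    means = means_counts / volume
    sems = np.sqrt(var_counts / n_runs) / volume
    return means, sems
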