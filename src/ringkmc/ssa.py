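"""Gillespie (kinetic Monte Carlo) simulation of the assembly network.

The direct-method stochastic simulation algorithm draws exponentially
distributed waiting times from the total propensity and picks the firing
channel proportionally to its propensity.  Bimolecular propensities follow
the particle-number convention ``a = k*nA*nB`` (distinct reactants) and
``a = (k/2)*nA*(nA-1)`` (identical reactants), which makes the mass-action
ODE of :mod:`ringkmc.network` the exact large-number limit.

Observed turnover is extracted from the ADP trace: the first half of a run
is discarded as burn-in, a linear fit of ADP vs time over the remainder
gives the production rate, and division by the number of wild-type
subunits yields k_obs per wild-type subunit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .inhibition import InhibitionScheme
from .network import ADP, RateTable, ReactionNetwork, Reaction, build_network

__all__ = [
    "AbsorbingState",
    "InsufficientData",
    "SimulationConfig",
    "Trace",
    "SteadyStateWindow",
    "step",
    "run",
    "steady_state_window",
    "kobs_from_trace",
    "oligomer_census",
    "hexamer_census",
    "ssa_propensities",
]


class AbsorbingState(Exception):
    """Raised by :func:`step` when the total propensity is zero."""


class InsufficientData(ValueError):
    """Raised when a trace is too short for steady-state analysis."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one stochastic run.

    ``record_every`` controls how often full species snapshots are stored
    (the ADP/time trace is always kept at event resolution, so the k_obs
    slope estimate is independent of the snapshot cadence).
    """

    n_Wt: int
    n_Mut: int = 0
    n_steps: int = 100_000
    seed: int = 0
    pathway: str = "1236"
    scheme: InhibitionScheme = field(default_factory=InhibitionScheme.scheme2)
    rates: RateTable = field(default_factory=RateTable)
    record_every: int | None = None

    def __post_init__(self) -> None:
        if self.n_Wt < 0 or self.n_Mut < 0 or self.n_Wt + self.n_Mut <= 0:
            raise ValueError("need a positive total number of subunits")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")

    @property
    def snapshot_cadence(self) -> int:
        if self.record_every is not None:
            return max(1, self.record_every)
        return max(1, self.n_steps // 5000)


@dataclass
class Trace:
    """Recorded output of one run.

    ``times``/``adp`` are event-resolution; ``species_counts`` holds full
    state snapshots (one row per snapshot, ADP included as a column) taken
    at ``snapshot_times``.
    """

    times: np.ndarray
    adp: np.ndarray
    snapshot_times: np.ndarray
    species_counts: np.ndarray
    network: ReactionNetwork
    config: SimulationConfig
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    @property
    def final_counts(self) -> np.ndarray:
        return self.species_counts[-1]


class SteadyStateWindow(NamedTuple):
    start: int
    warning: bool
    slopes: tuple[float, float]


def ssa_propensities(network: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    """Channel propensities under the particle-number convention."""
    r0, r1, kind, k, _ = network._rate_arrays()
    n0 = state[r0].astype(float)
    n1 = np.where(r1 >= 0, state[np.maximum(r1, 0)], 1).astype(float)
    return np.where(
        kind == 0, k * n0,
        np.where(kind == 1, k * n0 * n1, 0.5 * k * n0 * np.maximum(n0 - 1.0, 0.0)),
    )


def step(
    state: np.ndarray, network: ReactionNetwork, rng: np.random.Generator
) -> tuple[float, Reaction]:
    """Advance *state* by one SSA event, in place.

    Returns the exponentially distributed waiting time and the chosen
    reaction; raises :class:`AbsorbingState` when nothing can fire.
    """
    a = ssa_propensities(network, state)
    total = a.sum()
    if total <= 0.0:
        raise AbsorbingState("total propensity is zero")
    dt = rng.exponential(1.0 / total)
    j = int(np.searchsorted(np.cumsum(a), rng.random() * total, side="right"))
    j = min(j, len(a) - 1)
    rxn = network.reactions[j]
    _, _, _, _, S = network._rate_arrays()
    state += S[:, j].astype(state.dtype)
    return dt, rxn


@njit(cache=True)
def _ssa_core(state, r0, r1, kind, rate, col_ptr, row_idx, col_val,
              n_steps, u, record_every, times, adp_trace, adp_col, snaps, snap_steps):
    R = rate.shape[0]
    a = np.empty(R)
    t = 0.0
    times[0] = 0.0
    adp_trace[0] = state[adp_col]
    snaps[0] = state
    snap_steps[0] = 0
    n_snap = 1
    n_done = 0
    for s in range(n_steps):
        atot = 0.0
        for j in range(R):
            n0 = state[r0[j]]
            if kind[j] == 0:
                aj = rate[j] * n0
            elif kind[j] == 1:
                aj = rate[j] * n0 * state[r1[j]]
            else:
                aj = 0.5 * rate[j] * n0 * (n0 - 1.0)
            a[j] = aj
            atot += aj
        if atot <= 0.0:
            break
        dt = -np.log(1.0 - u[2 * s]) / atot
        target = u[2 * s + 1] * atot
        acc = 0.0
        chosen = R - 1
        for j in range(R):
            acc += a[j]
            if acc >= target:
                chosen = j
                break
        for p in range(col_ptr[chosen], col_ptr[chosen + 1]):
            state[row_idx[p]] += col_val[p]
        t += dt
        n_done = s + 1
        times[n_done] = t
        adp_trace[n_done] = state[adp_col]
        if n_done % record_every == 0:
            snaps[n_snap] = state
            snap_steps[n_snap] = n_done
            n_snap += 1
    return n_done, n_snap


def _kernel_inputs(network: ReactionNetwork):
    r0, r1, kind, k, S = network._rate_arrays()
    Si = S.astype(np.int64)
    col_ptr = [0]
    row_idx: list[int] = []
    col_val: list[int] = []
    for j in range(Si.shape[1]):
        rows = np.nonzero(Si[:, j])[0]
        row_idx.extend(rows.tolist())
        col_val.extend(Si[rows, j].tolist())
        col_ptr.append(len(row_idx))
    return (
        r0, r1, kind, k,
        np.array(col_ptr, dtype=np.int64),
        np.array(row_idx, dtype=np.int64),
        np.array(col_val, dtype=np.int64),
    )


def run(config: SimulationConfig, network: ReactionNetwork | None = None) -> Trace:
    """Run one stochastic trajectory from the all-monomer initial state."""
    if network is None:
        network = build_network(config.pathway, config.rates, config.scheme)
    state = network.initial_state(config.n_Wt, config.n_Mut).astype(np.int64)
    r0, r1, kind, k, col_ptr, row_idx, col_val = _kernel_inputs(network)
    rng = np.random.default_rng(config.seed)
    u = rng.random(2 * config.n_steps)
    cadence = config.snapshot_cadence
    n_rec = config.n_steps // cadence + 2
    times = np.zeros(config.n_steps + 1)
    adp_trace = np.zeros(config.n_steps + 1, dtype=np.int64)
    snaps = np.zeros((n_rec, len(network.species)), dtype=np.int64)
    snap_steps = np.zeros(n_rec, dtype=np.int64)
    adp_col = network.index[ADP]
    n_done, n_snap = _ssa_core(
        state, r0, r1, kind, k, col_ptr, row_idx, col_val,
        config.n_steps, u, cadence, times, adp_trace, adp_col, snaps, snap_steps,
    )
    absorbed = n_done < config.n_steps
    if snap_steps[n_snap - 1] != n_done:  # keep the final state
        snaps[n_snap] = state
        snap_steps[n_snap] = n_done
        n_snap += 1
    return Trace(
        times=times[: n_done + 1],
        adp=adp_trace[: n_done + 1].astype(float),
        snapshot_times=times[snap_steps[:n_snap]],
        species_counts=snaps[:n_snap],
        network=network,
        config=config,
        absorbed=absorbed,
    )


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2 or t[-1] == t[0]:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def steady_state_window(trace: Trace, min_points: int = 100) -> SteadyStateWindow:
    """Burn-in detection: discard the first half, check slope stationarity.

    The ADP slope over the third and fourth quarters of the trace must
    agree within 10%, otherwise the window carries a warning flag (the run
    may not have equilibrated).
    """
    n = len(trace.times)
    if n < min_points:
        raise InsufficientData(f"trace has {n} points, need >= {min_points}")
    half, q3 = n // 2, 3 * n // 4
    s3 = _slope(trace.times[half:q3], trace.adp[half:q3])
    s4 = _slope(trace.times[q3:], trace.adp[q3:])
    scale = max(abs(s3), abs(s4))
    warning = scale > 0.0 and abs(s3 - s4) > 0.10 * scale
    return SteadyStateWindow(start=half, warning=warning, slopes=(s3, s4))


def kobs_from_trace(
    trace: Trace, n_Wt: int | None = None, window: SteadyStateWindow | None = None
) -> float:
    """Per-wild-type-subunit turnover from the steady-state ADP slope."""
    if n_Wt is None:
        n_Wt = trace.config.n_Wt
    if n_Wt <= 0:
        raise ValueError("n_Wt must be positive")
    if window is None:
        window = steady_state_window(trace)
    i = window.start
    return _slope(trace.times[i:], trace.adp[i:]) / n_Wt


def oligomer_census(trace: Trace):
    """Fraction of subunits in each oligomeric state at every snapshot.

    Returns a pandas DataFrame indexed by snapshot time with one column
    per oligomer size class; rows sum to 1.
    """
    import pandas as pd

    net = trace.network
    kinds = ["monomer", "dimer", "trimer", "tetramer", "pentamer", "hexamer"]
    counts = trace.species_counts
    total = counts @ net.subunit_size
    data = {}
    for kind in kinds:
        cols = [i for i, s in enumerate(net.species) if s.kind == kind]
        if cols:
            data[kind] = (counts[:, cols] * net.subunit_size[cols]).sum(axis=1) / total
    return pd.DataFrame(data, index=trace.snapshot_times)


def hexamer_census(
    trace: Trace, window: SteadyStateWindow | None = None
) -> dict[int, float]:
    """Time-averaged ring counts per config_id over the steady-state window.

    Snapshots are piecewise-constant between recording points; each one is
    weighted by its holding time.
    """
    from .rings import enumerate_ring_configurations

    net = trace.network
    if window is None:
        window = steady_state_window(trace)
    t_start = trace.times[window.start]
    mask = trace.snapshot_times >= t_start
    if mask.sum() < 2:
        mask = np.ones(len(trace.snapshot_times), dtype=bool)
    t = trace.snapshot_times[mask]
    counts = trace.species_counts[mask]
    dt = np.diff(t)
    if dt.sum() == 0:
        weights = np.ones(len(t)) / len(t)
    else:
        weights = np.append(dt, 0.0) / dt.sum()
    census = {}
    for cfg in enumerate_ring_configurations(6):
        from .network import Species

        sp = Species("hexamer", cfg.canonical_sequence)
        if sp in net.index:
            census[cfg.config_id] = float(counts[:, net.index[sp]] @ weights)
    return census
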