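"""Replica-exchange Metropolis Monte Carlo sampler.

One Monte Carlo step (mcs) is one elementary move proposal per replica.
Replicas sit on a fixed temperature ladder; every ``exchange_period`` mcs
adjacent-temperature pairs (alternating even/odd pairing between sweeps)
attempt to swap conformations with probability
min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)]).  Each replica carries a token that
travels with its conformation; token round trips along the full ladder
diagnose replica-exchange mixing.

Reproducibility: every replica owns an independent RNG stream derived from
the master seed, plus one stream for exchange decisions, so a run is a pure
function of (seed, config) regardless of how replicas are scheduled between
exchange barriers.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model import Conformation, ModelParams, NativeTopology, enforce_bonds
from .potential import fraction_native, is_clash_free, total_energy

DEFAULT_RELAXATION_UNIT = 10 ** 9


def relaxation_mcs(total_mcs: int, unit: int = DEFAULT_RELAXATION_UNIT) -> int:
    """Monte Carlo steps assigned to relaxation (equilibration).

    Short runs (total < 2 units) equilibrate for their initial half; longer
    runs of n units (n >= 2) equilibrate for (n - 1) units, i.e. everything
    but the final unit.
    """
    total_mcs = int(total_mcs)
    if total_mcs < 2 * unit:
        return total_mcs // 2
    return total_mcs - unit


def make_temperature_ladder(t_min: float, t_max: float, n: int = 64,
                            t_melt: Optional[float] = None,
                            dense_factor: float = 3.0,
                            window: float = 0.1) -> np.ndarray:
    """Non-uniform temperature grid, denser around the melting temperature.

    The ladder is geometric (constant density in log T) with the density
    multiplied by ``dense_factor`` inside [(1-window)*t_melt,
    (1+window)*t_melt], which concentrates replicas where the energy
    distributions change fastest and must overlap for replica exchange.
    Without a melting estimate the grid is plainly geometric.
    """
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    if n < 2:
        raise ValueError("ladder needs at least 2 temperatures")
    grid = np.geomspace(t_min, t_max, 4096)
    dens = 1.0 / grid
    if t_melt is not None:
        lo, hi = (1.0 - window) * t_melt, (1.0 + window) * t_melt
        dens[(grid >= lo) & (grid <= hi)] *= dense_factor
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    ladder = np.interp(np.linspace(0, 1, n), cdf, grid)
    ladder[0], ladder[-1] = t_min, t_max
    return ladder


@dataclass
class RunConfig:
    """Replica-exchange run configuration."""

    temperatures: np.ndarray
    total_mcs: int
    exchange_period: int = 1000
    sample_period: int = 10000
    ltyp: bool = True
    start: str = "native"              # 'native' | 'denatured'
    seed: int = 0
    relaxation_unit: int = DEFAULT_RELAXATION_UNIT
    record_knots: bool = False
    knot_closures: int = 13
    start_conformation: Optional[Conformation] = None
    checkpoint_interval: Optional[int] = None   # mcs between checkpoints
    checkpoint_path: Optional[str] = None
    check_every: int = 100000          # mcs between integrity spot-checks

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 1:
            raise ValueError("temperatures must be a 1-D array")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.sample_period % self.exchange_period != 0:
            raise ValueError(
                "sample_period must be a multiple of exchange_period")
        if self.start not in ("native", "denatured"):
            raise ValueError("start must be 'native' or 'denatured'")

    @property
    def relaxation_mcs(self) -> int:
        return relaxation_mcs(self.total_mcs, self.relaxation_unit)


class ReplicaEnsemble:
    """Per-temperature replica states, tokens, and RNG streams."""

    def __init__(self, config: RunConfig, topo: NativeTopology,
                 params: ModelParams, start_coords: np.ndarray):
        self.config = config
        self.topo = topo
        self.params = params
        n_rep = config.temperatures.size
        self.coords = np.tile(start_coords[None, :, :], (n_rep, 1, 1))
        e0 = total_energy(start_coords, topo, params)
        self.energies = np.full(n_rep, e0)
        self.tokens = np.arange(n_rep)
        self.rngs = [np.random.default_rng([config.seed, r])
                     for r in range(n_rep)]
        self.exchange_rng = np.random.default_rng([config.seed, 1 << 20])
        self.mcs = 0
        self.sweep_parity = 0

    @property
    def n_replicas(self) -> int:
        return self.config.temperatures.size

    def conformation(self, r: int) -> Conformation:
        conf = Conformation(self.coords[r].copy(), float(self.energies[r]))
        conf.q = fraction_native(conf, self.topo, self.params)
        return conf

    # -- persistence (checkpoint/resume) ---------------------------------
    def state_dict(self) -> dict:
        return {
            "coords": self.coords.copy(),
            "energies": self.energies.copy(),
            "tokens": self.tokens.copy(),
            "mcs": self.mcs,
            "sweep_parity": self.sweep_parity,
            "rng_states": [r.bit_generator.state for r in self.rngs],
            "exchange_rng_state": self.exchange_rng.bit_generator.state,
        }

    def load_state_dict(self, state: dict):
        self.coords = state["coords"].copy()
        self.energies = state["energies"].copy()
        self.tokens = state["tokens"].copy()
        self.mcs = int(state["mcs"])
        self.sweep_parity = int(state["sweep_parity"])
        for rng, st in zip(self.rngs, state["rng_states"]):
            rng.bit_generator.state = st
        self.exchange_rng.bit_generator.state = state["exchange_rng_state"]

    def save_checkpoint(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self.state_dict(), fh)

    def load_checkpoint(self, path):
        with open(path, "rb") as fh:
            self.load_state_dict(pickle.load(fh))


def metropolis_step(ensemble: ReplicaEnsemble, r: int, n_steps: int = 1):
    """Advance replica r by n_steps mcs (rejections count as steps)."""
    cfg, topo, p = ensemble.config, ensemble.topo, ensemble.params
    e, n_acc = _kernels.mc_block(
        ensemble.coords[r], float(ensemble.energies[r]),
        float(cfg.temperatures[r]), int(n_steps),
        topo.ci, topo.cj, topo.native_distances,
        topo.chin_ij, topo.def_ij, topo.chin_ji, topo.def_ji,
        p.epsilon, p.w, p.bead_radius, cfg.ltyp, ensemble.rngs[r], False)
    if n_acc < 0:
        raise RuntimeError("LTyP trial conformation had a steric clash")
    ensemble.energies[r] = e
    return n_acc


def replica_exchange_sweep(ensemble: ReplicaEnsemble):
    """Attempt swaps on adjacent pairs (alternating even/odd pairing)."""
    t = ensemble.config.temperatures
    rng = ensemble.exchange_rng
    n_swapped = 0
    for i in range(ensemble.sweep_parity, ensemble.n_replicas - 1, 2):
        j = i + 1
        de = ensemble.energies[i] - ensemble.energies[j]
        dbeta = 1.0 / t[i] - 1.0 / t[j]
        if dbeta * de >= 0 or rng.random() < np.exp(dbeta * de):
            ensemble.coords[[i, j]] = ensemble.coords[[j, i]]
            ensemble.energies[[i, j]] = ensemble.energies[[j, i]]
            ensemble.tokens[[i, j]] = ensemble.tokens[[j, i]]
            n_swapped += 1
    ensemble.sweep_parity ^= 1
    return n_swapped


def _spot_check(ensemble: ReplicaEnsemble):
    """Assert accepted states are clash-free, bond-exact, energy-consistent."""
    topo, p = ensemble.topo, ensemble.params
    for r in range(ensemble.n_replicas):
        coords = ensemble.coords[r]
        dev = _kernels.max_bond_deviation(coords, topo.bond_lengths)
        if dev > 1e-6:
            raise RuntimeError(f"bond-length drift {dev:.2e} A in replica {r}")
        if not is_clash_free(coords, p):
            raise RuntimeError(f"steric clash in accepted state, replica {r}")
        e = total_energy(coords, topo, p)
        if abs(e - ensemble.energies[r]) > 1e-6:
            raise RuntimeError(
                f"energy cache drift {abs(e - ensemble.energies[r]):.2e} "
                f"in replica {r}")


def run_simulation(config: RunConfig, topo: NativeTopology,
                   params: ModelParams, resume_from: Optional[str] = None):
    """Run a replica-exchange simulation; return (samples, ensemble).

    Samples (one row per replica slot at every post-relaxation
    sample-period boundary) carry mcs, temperature index, token, E, Q and
    optionally the knotted flag.  Fully reproducible from (seed, config);
    resuming from a checkpoint continues bit-identically.
    """
    from .knots import is_knotted

    if config.start == "native":
        start = np.array(topo.native_coords)
    else:
        if config.start_conformation is None:
            raise ValueError("start='denatured' requires start_conformation "
                             "(see synthetic.generate_denatured)")
        start = np.array(config.start_conformation.coords)
        if is_knotted(start, config.knot_closures):
            raise ValueError("denatured start requested but the supplied "
                             "conformation is knotted")
    if start.shape[0] != topo.n_beads:
        raise ValueError("start conformation size does not match topology")
    start = enforce_bonds(start, topo.bond_lengths)
    if not is_clash_free(start, params):
        raise ValueError("start conformation has steric clashes")

    ensemble = ReplicaEnsemble(config, topo, params, start)
    if resume_from is not None:
        ensemble.load_checkpoint(resume_from)

    relax = config.relaxation_mcs
    period = config.exchange_period
    rows = []
    next_check = ((ensemble.mcs // config.check_every) + 1) \
        * config.check_every
    while ensemble.mcs < config.total_mcs:
        block = min(period, config.total_mcs - ensemble.mcs)
        for r in range(ensemble.n_replicas):
            metropolis_step(ensemble, r, block)
        ensemble.mcs += block
        if ensemble.mcs % period == 0:
            replica_exchange_sweep(ensemble)
        if ensemble.mcs > relax and ensemble.mcs % config.sample_period == 0:
            for r in range(ensemble.n_replicas):
                q = fraction_native(ensemble.coords[r], topo, params)
                row = {"mcs": ensemble.mcs, "replica": r, "T_index": r,
                       "token": int(ensemble.tokens[r]),
                       "E": float(ensemble.energies[r]), "Q": q}
                if config.record_knots:
                    row["knotted"] = is_knotted(ensemble.coords[r],
                                                config.knot_closures)
                rows.append(row)
        if ensemble.mcs >= next_check:
            _spot_check(ensemble)
            next_check += config.check_every
        if (config.checkpoint_interval and config.checkpoint_path
                and ensemble.mcs % config.checkpoint_interval == 0):
            ensemble.save_checkpoint(config.checkpoint_path)
    samples = pd.DataFrame(
        rows, columns=["mcs", "replica", "T_index", "token", "E", "Q"]
        + (["knotted"] if config.record_knots else []))
    return samples, ensemble


def token_roundtrips(samples: pd.DataFrame,
                     n_temperatures: Optional[int] = None) -> dict:
    """Completed bottom -> top -> bottom ladder traversals per token."""
    if "token" not in samples.columns:
        raise ValueError("sample table lacks a token column")
    n_t = n_temperatures or int(samples["T_index"].max()) + 1
    bottom, top = 0, n_t - 1
    counts = {}
    for token, grp in samples.sort_values("mcs").groupby("token"):
        state = 0  # 0: waiting for bottom, 1: going up, 2: coming down
        trips = 0
        for ti in grp["T_index"].to_numpy():
            if state == 0:
                if ti == bottom:
                    state = 1
            elif state == 1:
                if ti == top:
                    state = 2
            else:
                if ti == bottom:
                    trips += 1
                    state = 1
        counts[int(token)] = trips
    return counts


def estimate_melting(topo: NativeTopology, params: ModelParams,
                     t_lo: float, t_hi: float, n_temps: int = 8,
                     total_mcs: int = 200000, seed: int = 12345) -> float:
    """Pilot estimate of Tm: short non-LTyP run, peak of the direct CV(T)."""
    cfg = RunConfig(temperatures=make_temperature_ladder(t_lo, t_hi, n_temps),
                    total_mcs=total_mcs, exchange_period=500,
                    sample_period=500, ltyp=False, start="native", seed=seed,
                    relaxation_unit=DEFAULT_RELAXATION_UNIT)
    samples, _ = run_simulation(cfg, topo, params)
    cv = []
    for r, grp in samples.groupby("T_index"):
        e = grp["E"].to_numpy()
        cv.append(e.var() / cfg.temperatures[int(r)] ** 2)
    return float(cfg.temperatures[int(np.argmax(cv))])
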