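"""Replica-exchange sampler: Metropolis, swaps, scheduling, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_chain
from knotfold import _kernels, remc
from knotfold.model import ModelParams, NativeTopology
from knotfold.remc import (RunConfig, make_temperature_ladder, relaxation_mcs,
                           replica_exchange_sweep, run_simulation,
                           token_roundtrips)
from knotfold.synthetic import generate_denatured, make_toy_topology


@pytest.mark.parametrize("total,unit,expected", [
    (10 ** 8, 10 ** 9, 5 * 10 ** 7),     # short run: initial half
    (10 ** 9, 10 ** 9, 5 * 10 ** 8),
    (3 * 10 ** 9, 10 ** 9, 2 * 10 ** 9),  # n units, n >= 2: n-1 units
    (2 * 10 ** 9, 10 ** 9, 10 ** 9),
    (7 * 10 ** 9, 10 ** 9, 6 * 10 ** 9),
    (300000, 100000, 200000),             # test-scale unit, same rule
    (150000, 100000, 75000),
])
def test_relaxation_budget_rule(total, unit, expected):
    assert relaxation_mcs(total, unit) == expected


def test_temperature_ladder_shape():
    ladder = make_temperature_ladder(0.1, 1.0, 64, t_melt=0.4)
    assert ladder.size == 64
    assert ladder[0] == 0.1 and ladder[-1] == 1.0
    assert np.all(np.diff(ladder) > 0)
    # densification: spacing inside the melting window is finer than just
    # outside it
    inside = np.diff(ladder)[(ladder[:-1] > 0.37) & (ladder[:-1] < 0.43)]
    outside = np.diff(ladder)[(ladder[:-1] > 0.6) & (ladder[:-1] < 0.9)]
    assert inside.mean() < outside.mean()


def test_config_validation():
    with pytest.raises(ValueError):
        RunConfig(temperatures=[0.5, 0.4], total_mcs=1000)
    with pytest.raises(ValueError):
        RunConfig(temperatures=[0.4, 0.5], total_mcs=1000,
                  exchange_period=300, sample_period=1000)


def test_downhill_moves_always_accepted(hairpin, params):
    """With an empty contact map every clash-free proposal has dE = 0 <= 0
    and must be accepted; LTyP trials are clash-free by construction, so
    the acceptance rate is exactly 1."""
    topo = NativeTopology.from_coords(hairpin.native_coords, [])
    cfg = RunConfig(temperatures=[0.2, 0.5], total_mcs=1000,
                    exchange_period=1000, sample_period=1000, seed=3)
    ens = remc.ReplicaEnsemble(cfg, topo, params, hairpin.native_coords)
    n_acc = remc.metropolis_step(ens, 0, 500)
    assert n_acc == 500


def test_swap_probability_matches_closed_form(hairpin, params):
    """Two replicas with pinned energies: empirical swap rate equals
    min(1, exp[(1/T1 - 1/T2)(E1 - E2)]) within 1% over 1e5 attempts."""
    t1, t2, e1, e2 = 0.5, 1.0, -3.0, -1.0
    cfg = RunConfig(temperatures=[t1, t2], total_mcs=1000, seed=5,
                    exchange_period=1000, sample_period=1000)
    ens = remc.ReplicaEnsemble(cfg, hairpin, params, hairpin.native_coords)
    p_analytic = np.exp((1 / t1 - 1 / t2) * (e1 - e2))
    n_try, n_swap = 100000, 0
    for _ in range(n_try):
        ens.energies[:] = (e1, e2)
        ens.tokens[:] = (0, 1)
        ens.sweep_parity = 0
        replica_exchange_sweep(ens)
        n_swap += ens.tokens[0] == 1
    assert n_swap / n_try == pytest.approx(p_analytic, abs=0.01)
    # equal energies swap with probability 1
    ens.energies[:] = (-2.0, -2.0)
    ens.sweep_parity = 0
    ens.tokens[:] = (0, 1)
    replica_exchange_sweep(ens)
    assert list(ens.tokens) == [1, 0]


def test_tokens_remain_a_permutation(hairpin_run):
    cfg, samples, ensemble = hairpin_run
    assert sorted(ensemble.tokens) == list(range(cfg.temperatures.size))
    for _, tick in samples.groupby("mcs"):
        assert sorted(tick["token"]) == list(range(cfg.temperatures.size))


def test_run_is_deterministic(hairpin, params):
    ladder = make_temperature_ladder(0.2, 0.9, 4)
    kw = dict(temperatures=ladder, total_mcs=40000, exchange_period=500,
              sample_period=1000, ltyp=False, start="native", seed=99)
    s1, e1 = run_simulation(RunConfig(**kw), hairpin, params)
    s2, e2 = run_simulation(RunConfig(**kw), hairpin, params)
    pd.testing.assert_frame_equal(s1, s2)
    assert np.array_equal(e1.coords, e2.coords)


def test_checkpoint_resume_is_bit_identical(hairpin, params, tmp_path):
    ladder = make_temperature_ladder(0.2, 0.9, 4)
    ckpt = str(tmp_path / "state.pkl")
    kw = dict(temperatures=ladder, total_mcs=60000, exchange_period=500,
              sample_period=1000, ltyp=True, start="native", seed=17)
    full, ens_full = run_simulation(RunConfig(**kw), hairpin, params)
    # run the first half, checkpoint, then resume to the end
    half = RunConfig(**{**kw, "total_mcs": 30000})
    _, ens_half = run_simulation(half, hairpin, params)
    ens_half.save_checkpoint(ckpt)
    tail, ens_res = run_simulation(RunConfig(**kw), hairpin, params,
                                   resume_from=ckpt)
    assert np.array_equal(ens_full.coords, ens_res.coords)
    assert np.array_equal(ens_full.tokens, ens_res.tokens)
    pd.testing.assert_frame_equal(
        full[full.mcs > 30000].reset_index(drop=True),
        tail.reset_index(drop=True))


def test_denatured_start_guard(trefoil, params):
    cfg = RunConfig(temperatures=[0.2, 0.5], total_mcs=1000,
                    exchange_period=500, sample_period=500,
                    start="denatured", seed=1)
    with pytest.raises(ValueError, match="requires start_conformation"):
        run_simulation(cfg, trefoil, params)
    from knotfold.model import Conformation
    cfg.start_conformation = Conformation(trefoil.native_coords.copy())
    with pytest.raises(ValueError, match="knotted"):
        run_simulation(cfg, trefoil, params)


def test_token_roundtrips_on_synthetic_traces():
    # a token pinned to one slot never completes a trip
    pinned = pd.DataFrame({"mcs": np.arange(10), "token": 0,
                           "T_index": np.full(10, 2)})
    assert token_roundtrips(pinned, n_temperatures=4) == {0: 0}
    # alternating bottom/top each record: (records - 1) // 2 trips
    records = 11
    alt = pd.DataFrame({
        "mcs": np.arange(records), "token": 0,
        "T_index": np.where(np.arange(records) % 2 == 0, 0, 3)})
    assert token_roundtrips(alt, n_temperatures=4) == {0: (records - 1) // 2}


def test_mixing_diagnostic_on_toy_run(hairpin, params):
    """A well-mixed toy run completes at least one round trip per token."""
    ladder = make_temperature_ladder(0.25, 0.75, 4, t_melt=0.41)
    cfg = RunConfig(temperatures=ladder, total_mcs=300000,
                    exchange_period=200, sample_period=200, ltyp=False,
                    start="native", seed=23)
    samples, _ = run_simulation(cfg, hairpin, params)
    trips = token_roundtrips(samples, 4)
    assert all(v >= 1 for v in trips.values())


@pytest.mark.parametrize("ltyp", [True, False])
def test_zero_energy_chain_matches_rejection_oracle(ltyp, params):
    """With no contacts, the stationary distribution is uniform over
    clash-free chains; the sampled end-to-end distance must match a
    brute-force rejection sampler (KS test)."""
    n = 5
    rng = np.random.default_rng(2)
    start = random_chain(rng, n)
    topo = NativeTopology.from_coords(start, [])
    coords = start.copy()
    e = 0.0
    mc_rng = np.random.default_rng(10)
    # decorrelate: keep one sample every 40 mcs
    ee = []
    for _ in range(4000):
        e, _ = _kernels.mc_block(
            coords, e, 1.0, 40, topo.ci, topo.cj, topo.native_distances,
            topo.chin_ij, topo.def_ij, topo.chin_ji, topo.def_ji,
            params.epsilon, params.w, params.bead_radius, ltyp, mc_rng, False)
        ee.append(np.linalg.norm(coords[-1] - coords[0]))
    # oracle: uniform bond directions, rejected on clashes
    orc_rng = np.random.default_rng(20)
    oracle = []
    while len(oracle) < 4000:
        steps = orc_rng.normal(size=(n - 1, 3))
        steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
        pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if not _kernels.has_clash_full(pts, params.bead_radius):
            oracle.append(np.linalg.norm(pts[-1] - pts[0]))
    p = stats.ks_2samp(np.array(ee), np.array(oracle)).pvalue
    assert p > 0.01


def test_spot_check_catches_corrupted_state(hairpin, params):
    cfg = RunConfig(temperatures=[0.3, 0.6], total_mcs=1000,
                    exchange_period=500, sample_period=500, seed=2)
    ens = remc.ReplicaEnsemble(cfg, hairpin, params, hairpin.native_coords)
    ens.energies[0] += 1.0  # corrupt the cache
    with pytest.raises(RuntimeError, match="energy cache drift"):
        remc._spot_check(ens)


def test_generate_denatured_postconditions(hairpin, params):
    from knotfold.knots import is_knotted
    d1 = generate_denatured(hairpin, params, t_hot=1.2, budget_mcs=30000,
                            seed=5)
    d2 = generate_denatured(hairpin, params, t_hot=1.2, budget_mcs=30000,
                            seed=5)
    assert d1.q < 0.2
    assert not is_knotted(d1.coords)
    assert np.array_equal(d1.coords, d2.coords)
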