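import numpy as np
import pytest

from knotfold import remc, synthetic
from knotfold.model import ModelParams

BOND = 3.8
CLEARANCE = 3.4  # 2 x bead radius


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def hairpin():
    return synthetic.make_toy_topology("hairpin", 15)


@pytest.fixture(scope="session")
def trefoil():
    return synthetic.make_knotted_topology(35)


def random_chain(rng, n, bond=BOND, clearance=CLEARANCE):
    """Random clash-free chain with fixed bond length (rejection growth)."""
    while True:
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for _try in range(200):
                step = rng.normal(size=3)
                step *= bond / np.linalg.norm(step)
                cand = pts[-1] + step
                if len(pts) < 2 or np.all(np.linalg.norm(
                        np.asarray(pts[:-1]) - cand, axis=1) >= clearance):
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.asarray(pts)


@pytest.fixture(scope="session")
def hairpin_run(hairpin, params):
    """One short LTyP replica-exchange run on the hairpin toy, shared by
    sampler and WHAM tests."""
    ladder = remc.make_temperature_ladder(0.17, 0.95, 8, t_melt=0.41)
    cfg = remc.RunConfig(temperatures=ladder, total_mcs=300000,
                         exchange_period=500, sample_period=500,
                         ltyp=True, start="native", seed=7)
    samples, ensemble = remc.run_simulation(cfg, hairpin, params)
    return cfg, samples, ensemble
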