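import numpy as np
import pandas as pd
import pytest

from tempmort import bn


@pytest.fixture
def chain_model():
    """Known 3-node chain A -> B -> C with strong dependence."""
    states = {"A": ["0", "1"], "B": ["0", "1"], "C": ["0", "1"]}
    dag = bn.Dag(states, [("A", "B"), ("B", "C")])
    cpts = {
        "A": bn.Cpt("A", (), [[0.5, 0.5]]),
        "B": bn.Cpt("B", ("A",), [[0.9, 0.1], [0.1, 0.9]]),
        "C": bn.Cpt("C", ("B",), [[0.85, 0.15], [0.2, 0.8]]),
    }
    return bn.BnModel(dag, cpts)


@pytest.fixture
def toy_4node_model():
    """4-node model with a collider, 2 states each (16 joint states)."""
    states = {n: ["0", "1"] for n in "ABCD"}
    dag = bn.Dag(states, [("A", "C"), ("B", "C"), ("C", "D")])
    cpts = {
        "A": bn.Cpt("A", (), [[0.3, 0.7]]),
        "B": bn.Cpt("B", (), [[0.6, 0.4]]),
        "C": bn.Cpt("C", ("A", "B"),
                    [[0.9, 0.1], [0.7, 0.3], [0.4, 0.6], [0.1, 0.9]]),
        "D": bn.Cpt("D", ("C",), [[0.8, 0.2], [0.25, 0.75]]),
    }
    return bn.BnModel(dag, cpts)


def make_daily_series(n_days=400, deaths=None, tmean=None, start="2010-01-01",
                      rh=None, region_id="R00"):
    """Minimal valid daily region series for unit tests."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    if tmean is None:
        tmean = 15.0 + 10.0 * np.sin(2 * np.pi * np.arange(n_days) / 365.25)
    tmean = np.broadcast_to(np.asarray(tmean, float), (n_days,))
    if rh is None:
        rh = 70.0 + 10.0 * np.cos(2 * np.pi * np.arange(n_days) / 365.25)
    df = pd.DataFrame({
        "region_id": region_id, "date": dates, "tmean": tmean,
        "tmax": tmean + 4.0, "tmin": tmean - 4.0,
        "rh": np.broadcast_to(np.asarray(rh, float), (n_days,)),
    })
    if deaths is not None:
        df["deaths"] = deaths
    return df


def enumerate_joint_bruteforce(model):
    """Independent oracle: joint table by explicit CPT-product loops."""
    import itertools

    nodes = model.dag.nodes
    out = {}
    for combo in itertools.product(*(model.dag.states[n] for n in nodes)):
        a = dict(zip(nodes, combo))
        p = 1.0
        for n in nodes:
            cpt = model.cpts[n]
            row = 0
            for par in cpt.parents:
                row = row * len(model.dag.states[par]) + model.dag.states[par].index(a[par])
            p *= cpt.table[row][model.dag.states[n].index(a[n])]
        out[combo] = p
    return nodes, out
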