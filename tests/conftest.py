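import numpy as np
import pytest

from minnet.model_io import MetabolicNetwork


def network_from_dict(mets, reactions):
    """Build a MetabolicNetwork from {rid: (stoich dict, lb, ub)}."""
    rids = list(reactions)
    S = np.zeros((len(mets), len(rids)))
    l = np.zeros(len(rids))
    u = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        stoich, lo, hi = reactions[rid]
        for m, coef in stoich.items():
            S[mets.index(m), j] = coef
        l[j], u[j] = lo, hi
    return MetabolicNetwork(mets, rids, S, l, u)


@pytest.fixture
def linear_chain():
    """up -> A -> B -> export, all irreversible."""
    return network_from_dict(
        ["A", "B"],
        {
            "up": ({"A": 1}, 0, 10),
            "conv": ({"A": -1, "B": 1}, 0, 10),
            "ex": ({"B": -1}, 0, 10),
        })
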