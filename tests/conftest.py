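import numpy as np
import pytest

from metamod.network import MetabolicNetwork
from metamod.scores import AnnotatedNetwork, BumFit
from metamod.scores import fdr_threshold_params


def make_fit(a: float, lam: float, fdr_level: float = 0.1) -> BumFit:
    """A mixture fit object with the given parameters and a consistent tau."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = fdr_threshold_params(a, lam, fdr_level)
    return BumFit(a=a, lam=lam, tau=tau, loglik=0.0, n=0, fdr_level=fdr_level)


@pytest.fixture
def toy_net() -> MetabolicNetwork:
    """E1-M1-E2-M2 path plus a pendant E3 on M2."""
    return MetabolicNetwork.from_edges(
        [("E1", "M1"), ("E2", "M1"), ("E2", "M2"), ("E3", "M2")]
    )


@pytest.fixture
def fully_observed(toy_net) -> AnnotatedNetwork:
    return AnnotatedNetwork(toy_net, {v: 0.5 for v in toy_net.nodes})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
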