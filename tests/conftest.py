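import numpy as np
import pytest

from mama.pipeline import DiscoveryConfig, discover
from mama.scoring import ScoringParams
from mama.sequence_io import ExpressionTable, PromoterSet
from mama.synth import benchmark_scenario, generate


def random_promoters(rng, n_genes=20, length=80, n_prob=0.0, region=None):
    probs = [(1 - n_prob) / 4] * 4 + [n_prob]
    records = {
        f"g{i:03d}": "".join(rng.choice(list("ACGTN"), p=probs, size=length))
        for i in range(n_genes)
    }
    region = region or (-length, 0)
    return PromoterSet(region=region, records=records)


def random_expression(rng, gene_ids, low=0.2, high=8.0):
    return ExpressionTable({g: float(rng.uniform(low, high)) for g in gene_ids})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_promoters(rng):
    return random_promoters(rng)


@pytest.fixture
def small_expression(rng, small_promoters):
    return random_expression(rng, small_promoters.gene_ids)


@pytest.fixture(scope="session")
def single_motif_data():
    return generate(benchmark_scenario("single_motif", seed=11))


@pytest.fixture(scope="session")
def single_motif_discovery(single_motif_data):
    promoters, expr, _truth = single_motif_data
    return discover(promoters, expr, ScoringParams(), DiscoveryConfig(top_k=20))
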