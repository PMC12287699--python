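import numpy as np
import pytest

from selcnn.encoding import EncodedExample
from selcnn.simulate import (
    GeneProfile,
    IndelModel,
    SimulationConfig,
    build_codon_model,
    simulate_gene,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def baseline_config():
    return SimulationConfig()


def make_profile(
    gene_class="positive",
    kappa=2.5,
    omegas=(0.3, 0.7, 3.0),
    p0=0.6,
    p2=0.05,
    root_length=120,
):
    return GeneProfile(
        kappa=kappa,
        omega0=omegas[0],
        omega1=omegas[1],
        omega2=omegas[2],
        p0=p0,
        p1=1.0 - p0 - p2,
        p2=p2,
        root_length=root_length,
        gene_class=gene_class,
    )


@pytest.fixture(scope="session")
def small_gene_records(baseline_config):
    """A handful of simulated genes shared across I/O and codec tests."""
    tree = baseline_config.tree()
    indel = IndelModel(rate=0.1)
    gen = np.random.default_rng(7)
    records = []
    for k, cls in enumerate(["positive", "purifying", "neutral", "positive"]):
        profile = make_profile(gene_class=cls, root_length=100 + 10 * k)
        model = build_codon_model(profile)
        records.append(
            simulate_gene(profile, tree, model, indel, gen, gene_id=f"g{k}")
        )
    return records


def random_example(rng, n=8, length=30, label=1, gene_id=""):
    tensor = np.zeros((n, length, 5), dtype=np.uint8)
    idx = rng.integers(0, 5, size=(n, length))
    tensor[np.arange(n)[:, None], np.arange(length)[None, :], idx] = 1
    return EncodedExample(tensor=tensor, label=label, gene_id=gene_id)
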