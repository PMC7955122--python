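"""Shared fixtures: small simulated panels and trained models.

Session-scoped so that expensive trainings are reused across test modules.
Problem sizes are deliberately small (hundreds of haplotypes, tens of SNVs)
to keep the noiseless/noisy regimes cleanly separated while the whole suite
stays quick.
"""

import numpy as np
import pytest

import hlaconv as h

# compact network: plenty of capacity for the synthetic panels
SMALL_HP = dict(
    conv1_filters=12,
    conv2_filters=12,
    kernel1=5,
    kernel2=3,
    shared_fc_units=32,
    dropout_rate=0.15,
    batch_size=64,
    learning_rate=2e-3,
    max_epochs=30,
    patience=5,
)


def small_hp(**over) -> h.ModelHyperparams:
    kw = {**SMALL_HP, **over}
    return h.ModelHyperparams(**kw)


@pytest.fixture(scope="session")
def noiseless_sim() -> h.SimulatedReference:
    """Two genes x four alleles, perfect tagging: fully decodable."""
    cfg = h.SimConfig(n_haplotypes=400, n_snvs_per_group=80, seed=3)
    return h.simulate_reference_panel(cfg)


@pytest.fixture(scope="session")
def noiseless_model(noiseless_sim) -> h.TrainedGroupModel:
    return h.train_group(noiseless_sim.panel, noiseless_sim.group, small_hp(seed=0),
                         resolution=4)


@pytest.fixture(scope="session")
def noisy_sim() -> h.SimulatedReference:
    """Same geometry with 5% SNV noise and imperfect tagging."""
    cfg = h.SimConfig(
        n_haplotypes=400,
        n_snvs_per_group=80,
        tagging_fidelity=0.92,
        snv_noise_rate=0.05,
        seed=11,
    )
    return h.simulate_reference_panel(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_probs(rng, n_samples=20, genes=("G1", "G2"), k=4) -> h.AlleleProbabilities:
    """Random softmax probability fixture over synthetic allele names."""
    names = [f"{i // 2 + 1:02d}:{i % 2 + 1:02d}" for i in range(k)]
    probs, alleles = {}, {}
    for g in genes:
        z = rng.normal(size=(2 * n_samples, k)) * 2.0
        e = np.exp(z - z.max(axis=1, keepdims=True))
        probs[g] = e / e.sum(axis=1, keepdims=True)
        alleles[g] = list(names)
    return h.AlleleProbabilities([f"s{i}" for i in range(n_samples)], probs, alleles)


def random_truth(rng, n_samples=20, genes=("G1", "G2"), k=4) -> dict:
    names = np.array([f"{i // 2 + 1:02d}:{i % 2 + 1:02d}" for i in range(k)], dtype=object)
    return {g: names[rng.integers(k, size=(n_samples, 2))] for g in genes}
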