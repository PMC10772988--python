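"""Shared fixtures: tiny randomly-initialized models and one real training
run on the synthetic Arrhenius benchmark (session-scoped, reused by the
training/importance tests)."""

import numpy as np
import pytest

import thermokcat as tk
from thermokcat.train import TrainConfig


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained model with vocabularies grown from a couple of inputs."""
    atom_vocab, kmer_vocab = tk.TokenVocab(), tk.TokenVocab()
    for smi in ("CCO", "c1ccccc1O", "CC(=O)O", "NC(CO)C(=O)O"):
        tk.smiles_to_graph(smi, atom_vocab)
    for seq in ("MKVLAAGGYTRW", "ACDEFGHIKLMNPQRSTVWY"):
        tk.protein_to_kmers(seq, kmer_vocab)
    stats = tk.fit_thermo_stats([10.0, 25.0, 40.0, 60.0])
    config = tk.ModelConfig(H_c=16, H_c_prime=8, H_p=16, conv_layers=2,
                            d=8, dense_layers=3, fp_hidden=32, seed=3)
    return tk.KcatModel(config, atom_vocab, kmer_vocab, stats=stats)


@pytest.fixture(scope="session")
def arrhenius_benchmark():
    """The synthetic benchmark: 60 pairs x 6 temperatures, sigma=0.1."""
    spec = tk.ArrheniusSpec(seed=7)
    ds = tk.generate_arrhenius_dataset(spec)
    train, val, test = tk.split(ds.entries, (0.8, 0.1, 0.1), seed=7)
    return ds, train, val, test


@pytest.fixture(scope="session")
def trained_small(arrhenius_benchmark):
    """Small-config model trained on the benchmark (15 epochs, Adam)."""
    _, train, val, _ = arrhenius_benchmark
    train = tk.oversample(train, seed=7)
    model, history = tk.train_model(train, val, tk.ModelConfig.small(seed=7),
                                    TrainConfig(epochs=15, seed=7))
    return model, history
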