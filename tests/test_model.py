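"""Architecture tests: shapes, attention simplexes, the nested-loop oracle
for the bidirectional attention equations, permutation equivariance and
checkpoint round-trips."""

import numpy as np
import pytest

import thermokcat as tk
from thermokcat import autodiff as ad
from thermokcat.autodiff import Tensor
from thermokcat.model import (Batch, bidirectional_attention, cnn_encode,
                              collate, fingerprint_encode, forward,
                              gat_encode, init_params)

from oracles import loop_attention_full


def make_batch(rng, n_atoms, n_kmers, atom_vocab=5, kmer_vocab=7,
               n_edges=None, thermo=None):
    """Random single-sample batch with full masks."""
    adj = np.zeros((1, n_atoms, n_atoms))
    adj[0, np.arange(n_atoms), np.arange(n_atoms)] = 1.0
    if n_edges is None:
        n_edges = max(0, n_atoms - 1)
    for _ in range(n_edges):
        i, j = rng.integers(0, n_atoms, 2)
        if i != j:
            adj[0, i, j] = adj[0, j, i] = 1.0
    return Batch(
        atom_tokens=rng.integers(0, atom_vocab, (1, n_atoms)),
        atom_mask=np.ones((1, n_atoms, 1)),
        adj=adj,
        kmer_tokens=rng.integers(0, kmer_vocab, (1, n_kmers)),
        res_mask=np.ones((1, n_kmers, 1)),
        fp=rng.integers(0, 2, (1, 1024)).astype(float),
        thermo=np.asarray(thermo if thermo is not None else rng.uniform(size=(1, 2))),
    )


def small_config(d=8, seed=0):
    return tk.ModelConfig(H_c=10, H_c_prime=6, H_p=12, conv_layers=2, d=d,
                          dense_layers=3, fp_hidden=16, seed=seed)


def test_config_validation():
    with pytest.raises(ValueError):
        tk.ModelConfig(dense_layers=2)
    with pytest.raises(ValueError):
        tk.ModelConfig(conv_kernel=4)
    widths = tk.ModelConfig(d=64, dense_layers=4).dense_widths()
    assert widths[0] == 3 * 64 + 2 and widths[-1] == 1 and len(widths) == 5


def test_encoder_output_shapes():
    rng = np.random.default_rng(0)
    cfg = small_config()
    params = init_params(cfg, 5, 7)
    b = make_batch(rng, 4, 6)
    assert gat_encode(b, params, cfg).shape == (1, 4, cfg.H_c)
    assert cnn_encode(b, params, cfg).shape == (1, 6, cfg.H_p)
    assert fingerprint_encode(b.fp, params, cfg).shape == (1, cfg.H_c)
    with pytest.raises(ValueError):
        fingerprint_encode(np.zeros((1, 512)), params, cfg)


def test_full_size_width_defaults():
    """Default widths: per-atom 80, per-residue 80, per-head GAT output 50."""
    cfg = tk.ModelConfig()
    assert (cfg.H_c, cfg.H_c_prime, cfg.H_p) == (80, 50, 80)
    assert (cfg.gat_heads, cfg.attn_heads) == (3, 3)
    rng = np.random.default_rng(1)
    params = init_params(cfg, 5, 7)
    b = make_batch(rng, 3, 4)
    assert gat_encode(b, params, cfg).shape == (1, 3, 80)
    assert cnn_encode(b, params, cfg).shape == (1, 4, 80)


def test_single_atom_attends_to_itself():
    rng = np.random.default_rng(2)
    cfg = small_config()
    params = init_params(cfg, 5, 7)
    b = make_batch(rng, 1, 3, n_edges=0)
    _, attns = gat_encode(b, params, cfg, return_attention=True)
    for a in attns:
        assert a[0, 0, 0] == pytest.approx(1.0)


def test_gat_attention_rows_are_simplexes():
    rng = np.random.default_rng(3)
    cfg = small_config()
    params = init_params(cfg, 5, 7)
    b = make_batch(rng, 5, 4)
    _, attns = gat_encode(b, params, cfg, return_attention=True)
    for a in attns:
        np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-5)
        assert (a >= 0).all()


def test_attention_matches_loop_oracle():
    """Vectorized bidirectional attention equals the nested-loop reference
    on random small instances (to 1e-6)."""
    rng = np.random.default_rng(4)
    for trial in range(20):
        d = int(rng.integers(2, 9))
        cfg = small_config(d=d, seed=trial)
        params = init_params(cfg, 5, 7)
        nv, nr = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        b = make_batch(rng, nv, nr)
        V = Tensor(rng.normal(size=(1, nv, cfg.H_c)))
        R = Tensor(rng.normal(size=(1, nr, cfg.H_p)))
        f = Tensor(rng.normal(size=(1, cfg.H_c)))
        out = bidirectional_attention(V, R, f, b, params, cfg)
        ref = loop_attention_full(V.data[0], R.data[0], params, cfg)
        np.testing.assert_allclose(out.alpha_a2r[:, 0, :], ref["alpha_a2r"], atol=1e-6)
        np.testing.assert_allclose(out.alpha_r2a[:, 0, :], ref["alpha_r2a"], atol=1e-6)
        np.testing.assert_allclose(out.A[:, 0], ref["A"], atol=1e-6)
        np.testing.assert_allclose(out.h_c_final.data[0], ref["h_c_final"], atol=1e-6)
        np.testing.assert_allclose(out.h_p_final.data[0], ref["h_p_final"], atol=1e-6)


def test_attention_singletons_and_zero_vector():
    rng = np.random.default_rng(5)
    cfg = small_config()
    params = init_params(cfg, 5, 7)
    b = make_batch(rng, 1, 1, n_edges=0)
    V = Tensor(rng.normal(size=(1, 1, cfg.H_c)))
    R = Tensor(rng.normal(size=(1, 1, cfg.H_p)))
    f = Tensor(rng.normal(size=(1, cfg.H_c)))
    out = bidirectional_attention(V, R, f, b, params, cfg)
    np.testing.assert_allclose(out.alpha_a2r, 1.0)
    np.testing.assert_allclose(out.alpha_r2a, 1.0)
    assert np.abs(out.A).max() <= 1.0

    # zero attention vector -> uniform residue weights
    nr = 5
    b = make_batch(rng, 3, nr)
    for h in range(cfg.attn_heads):
        params[f"att{h}_ar2a"].data[:] = 0.0
    V = Tensor(rng.normal(size=(1, 3, cfg.H_c)))
    R = Tensor(rng.normal(size=(1, nr, cfg.H_p)))
    out = bidirectional_attention(V, R, f, b, params, cfg)
    np.testing.assert_allclose(out.alpha_r2a, 1.0 / nr, atol=1e-12)


def test_attention_simplexes_with_padding():
    """Padded positions get zero attention; valid positions still sum to 1."""
    rng = np.random.default_rng(6)
    cfg = small_config()
    params = init_params(cfg, 6, 9)
    g1 = tk.smiles_to_graph("CCO", tk.TokenVocab())
    g2 = tk.smiles_to_graph("C", tk.TokenVocab())
    vocab = tk.TokenVocab()
    t1 = tk.protein_to_kmers("MKVLA", vocab)
    t2 = tk.protein_to_kmers("MKV", vocab)
    th = tk.ThermoFeatures(0.3, 0.7, 300.0)
    b = collate([g1, g2], [t1, t2], [th, th])
    with ad.no_grad():
        _, att = forward(b, params, cfg, return_attention=True)
    np.testing.assert_allclose(att.alpha_r2a.sum(axis=-1), 1.0, atol=1e-5)
    np.testing.assert_allclose(att.alpha_a2r.sum(axis=-1), 1.0, atol=1e-5)
    assert att.alpha_a2r[:, 1, 1:].max() < 1e-12    # padded atoms of "C"
    assert att.alpha_r2a[:, 1, 1:].max() < 1e-12    # padded windows of "MKV"


def predict_entry(model, smiles, seq, t):
    return model.predict_single(smiles, seq, t)


def test_prediction_deterministic_and_finite(tiny_model):
    p1 = predict_entry(tiny_model, "CCO", "MKVLAAGGYTRW", 25.0)
    p2 = predict_entry(tiny_model, "CCO", "MKVLAAGGYTRW", 25.0)
    assert p1 == p2
    assert np.isfinite(p1)


def test_outputs_finite_for_many_random_inputs():
    """No NaN/Inf propagation across random graphs/sequences/temperatures."""
    rng = np.random.default_rng(7)
    cfg = small_config()
    params = init_params(cfg, 8, 11)
    with ad.no_grad():
        for lo in range(0, 1000, 100):
            bs = []
            for _ in range(100):
                bs.append((int(rng.integers(1, 7)), int(rng.integers(1, 9))))
            nv = max(b[0] for b in bs)
            nr = max(b[1] for b in bs)
            batch = Batch(
                atom_tokens=rng.integers(0, 8, (100, nv)),
                atom_mask=np.array([[[1.0]] * a + [[0.0]] * (nv - a) for a, _ in bs]),
                adj=np.tile(np.eye(nv), (100, 1, 1)),
                kmer_tokens=rng.integers(0, 11, (100, nr)),
                res_mask=np.array([[[1.0]] * r + [[0.0]] * (nr - r) for _, r in bs]),
                fp=rng.integers(0, 2, (100, 1024)).astype(float),
                thermo=rng.uniform(-0.5, 1.5, (100, 2)),
            )
            out = forward(batch, params, cfg)
            assert np.isfinite(out.data).all()


def permute_graph(g: tk.CompoundGraph, perm):
    inv = np.argsort(perm)
    return tk.CompoundGraph(
        atom_tokens=[g.atom_tokens[i] for i in perm],
        edges=[(int(inv[i]), int(inv[j])) for i, j in g.edges],
        fingerprint=g.fingerprint, n_atoms=g.n_atoms)


def test_whole_model_permutation_invariance(tiny_model):
    """Relabeling atoms must not change the prediction (GAT equivariance +
    permutation-invariant attention pooling)."""
    rng = np.random.default_rng(8)
    model = tiny_model
    g = tk.smiles_to_graph("NC(CO)C(=O)O", model.atom_vocab)
    tkn = tk.protein_to_kmers("MKVLAAGGYTRW", model.kmer_vocab)
    th = tk.normalize_temperature(30.0, model.stats)
    base = model.predict_batch(collate([g], [tkn], [th]))[0]
    for _ in range(5):
        perm = rng.permutation(g.n_atoms)
        gp = permute_graph(g, perm)
        p = model.predict_batch(collate([gp], [tkn], [th]))[0]
        assert abs(p - base) <= 1e-5


def test_gat_permutation_equivariance():
    rng = np.random.default_rng(9)
    cfg = small_config()
    params = init_params(cfg, 6, 7)
    vocab = tk.TokenVocab()
    g = tk.smiles_to_graph("CC(=O)C(=O)O", vocab)
    t = tk.ThermoFeatures(0.5, 0.5, 300.0)
    tkn = tk.ProteinTokens([0, 1, 2], 3)
    b = collate([g], [tkn], [t])
    V = gat_encode(b, params, cfg).data[0]
    perm = rng.permutation(g.n_atoms)
    bp = collate([permute_graph(g, perm)], [tkn], [t])
    Vp = gat_encode(bp, params, cfg).data[0]
    np.testing.assert_allclose(Vp, V[perm], atol=1e-6)


def test_temperature_ablation(tiny_model):
    """Zeroing the two temperature columns of the first dense layer makes
    predictions temperature-invariant."""
    model = tiny_model
    saved = model.params["dense0_W"].data.copy()
    try:
        model.params["dense0_W"].data[-2:, :] = 0.0
        p_cold = model.predict_single("CCO", "MKVLAAGGYTRW", 10.0)
        p_hot = model.predict_single("CCO", "MKVLAAGGYTRW", 60.0)
        assert p_cold == pytest.approx(p_hot, abs=1e-12)
    finally:
        model.params["dense0_W"].data = saved
    assert model.predict_single("CCO", "MKVLAAGGYTRW", 10.0) != pytest.approx(
        model.predict_single("CCO", "MKVLAAGGYTRW", 60.0), abs=1e-12)


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = tk.KcatModel.load(path)
    assert loaded.config == tiny_model.config
    p1 = tiny_model.predict_single("CCO", "MKVLAAGGYTRW", 25.0)
    p2 = loaded.predict_single("CCO", "MKVLAAGGYTRW", 25.0)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_checkpoint_mismatch_fails_loudly(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    import json
    import numpy as np_
    with np_.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    meta["config"]["d"] = 16   # config no longer matches stored shapes
    arrays["__meta__"] = np_.frombuffer(json.dumps(meta).encode(), dtype=np_.uint8)
    np_.savez(path, **arrays)
    with pytest.raises(ValueError, match="checkpoint"):
        tk.KcatModel.load(path)
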