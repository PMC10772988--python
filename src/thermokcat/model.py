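"""Neural architecture for temperature-dependent log10(kcat) regression.

The model couples three encoders and a bidirectional attention block:

* a graph attention network (GAT, 3 heads) over the substrate molecular
  graph, producing per-atom features v_i in R^{H_c};
* a stack of same-padded 1-D convolutions over protein 3-mer embeddings,
  producing per-residue(-window) features r_i in R^{H_p};
* a multilayer perceptron over the 1024-bit circular fingerprint, giving a
  whole-molecule vector f in R^{H_c};
* multi-head bidirectional attention: per head, atoms and residues are
  projected to a shared latent dimension d, a soft alignment matrix
  A = tanh(C U P^T) couples them, and softmax attention weights are computed
  in both the residue-to-atom (alpha_r2a) and atom-to-residue (alpha_a2r)
  directions; attention-weighted sums give compound and protein summary
  vectors, concatenated over heads and projected back to d.

The regressor consumes h_c_final || h_f || h_p_final || [T_norm, (1/T)_norm]
(width 3d+2) through dense layers with leaky-ReLU activations and a linear
output, predicting log10(kcat / s^-1).  Normalized T and 1/T enter late so
the temperature response rides on top of the pair representation, mirroring
the Arrhenius dependence of turnover numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, embedding, masked_softmax, shift
from .featurize import (CompoundGraph, NormalizationStats, ProteinTokens,
                        ThermoFeatures, TokenVocab, normalize_temperature,
                        protein_to_kmers, smiles_to_graph)

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the architecture.

    Defaults follow the published configuration: compound width H_c=80,
    per-head GAT output H_c'=50 with 3 heads, protein width H_p=80 with four
    convolutional layers, latent dimension d (40 or 64), 3 attention heads,
    and 3-6 dense layers.
    """

    H_c: int = 80
    H_c_prime: int = 50
    gat_heads: int = 3
    H_p: int = 80
    conv_layers: int = 4
    conv_kernel: int = 3
    d: int = 64
    attn_heads: int = 3
    dense_layers: int = 4
    fp_hidden: int = 256
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("H_c", "H_c_prime", "gat_heads", "H_p", "conv_layers",
                     "d", "attn_heads", "fp_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd (same-padding)")
        if not 3 <= self.dense_layers <= 6:
            raise ValueError("dense_layers must be in [3, 6]")

    @classmethod
    def small(cls, seed: int = 0) -> "ModelConfig":
        """Compact configuration for desk-scale experiments on one CPU."""
        return cls(H_c=64, H_c_prime=32, H_p=64, conv_layers=2, d=40,
                   dense_layers=3, fp_hidden=128, seed=seed)

    def dense_widths(self) -> list[int]:
        """Geometrically tapering dense widths from 3d+2 down to 1."""
        in_dim = 3 * self.d + 2
        w = np.geomspace(in_dim, 1.0, self.dense_layers + 1)
        return [max(1, int(round(x))) for x in w]


@dataclass
class Batch:
    """Padded, masked mini-batch of featurized compound-protein-T inputs."""

    atom_tokens: np.ndarray   # (B, Nv) int
    atom_mask: np.ndarray     # (B, Nv, 1) float 0/1
    adj: np.ndarray           # (B, Nv, Nv) float 0/1, self-loops included
    kmer_tokens: np.ndarray   # (B, Nr) int
    res_mask: np.ndarray      # (B, Nr, 1) float 0/1
    fp: np.ndarray            # (B, 1024) float
    thermo: np.ndarray        # (B, 2) float: [t_norm, invt_norm]

    @property
    def size(self) -> int:
        return self.atom_tokens.shape[0]


def collate(graphs: list[CompoundGraph], tokens: list[ProteinTokens],
            thermo: list[ThermoFeatures]) -> Batch:
    """Pad a list of featurized samples to the per-batch maximum.

    Padded atoms keep a self-loop in the adjacency so softmax rows stay
    well-defined; their outputs are zeroed by the masks downstream.
    """
    B = len(graphs)
    nv = max(g.n_atoms for g in graphs)
    nr = max(t.n_kmers for t in tokens)
    atom_tokens = np.zeros((B, nv), dtype=np.intp)
    atom_mask = np.zeros((B, nv, 1))
    adj = np.zeros((B, nv, nv))
    kmer_tokens = np.zeros((B, nr), dtype=np.intp)
    res_mask = np.zeros((B, nr, 1))
    fp = np.zeros((B, 1024))
    th = np.zeros((B, 2))
    for b, (g, t, f) in enumerate(zip(graphs, tokens, thermo)):
        atom_tokens[b, :g.n_atoms] = g.atom_tokens
        atom_mask[b, :g.n_atoms, 0] = 1.0
        adj[b, np.arange(nv), np.arange(nv)] = 1.0
        for i, j in g.edges:
            adj[b, i, j] = 1.0
            adj[b, j, i] = 1.0
        kmer_tokens[b, :t.n_kmers] = t.kmer_tokens
        res_mask[b, :t.n_kmers, 0] = 1.0
        fp[b] = g.fingerprint
        th[b] = (f.t_norm, f.invt_norm)
    return Batch(atom_tokens, atom_mask, adj, kmer_tokens, res_mask, fp, th)


# -- parameter initialisation -------------------------------------------------

def init_params(config: ModelConfig, atom_vocab_size: int,
                kmer_vocab_size: int) -> dict[str, Tensor]:
    """Create all learnable parameters with Xavier-style uniform init."""
    rng = np.random.default_rng(config.seed)
    p: dict[str, Tensor] = {}
    p["atom_emb"] = ad.xavier_uniform((atom_vocab_size, config.H_c), rng)
    p["kmer_emb"] = ad.xavier_uniform((kmer_vocab_size, config.H_p), rng)
    for h in range(config.gat_heads):
        p[f"gat{h}_W"] = ad.xavier_uniform((config.H_c, config.H_c_prime), rng)
        p[f"gat{h}_a_src"] = ad.xavier_uniform((config.H_c_prime, 1), rng)
        p[f"gat{h}_a_dst"] = ad.xavier_uniform((config.H_c_prime, 1), rng)
    p["gat_proj_W"] = ad.xavier_uniform(
        (config.gat_heads * config.H_c_prime, config.H_c), rng)
    p["gat_proj_b"] = ad.zeros((config.H_c,))
    half = config.conv_kernel // 2
    for layer in range(config.conv_layers):
        for o in range(-half, half + 1):
            p[f"conv{layer}_W{o}"] = ad.xavier_uniform((config.H_p, config.H_p), rng)
        p[f"conv{layer}_b"] = ad.zeros((config.H_p,))
    p["fp_W1"] = ad.xavier_uniform((1024, config.fp_hidden), rng)
    p["fp_b1"] = ad.zeros((config.fp_hidden,))
    p["fp_W2"] = ad.xavier_uniform((config.fp_hidden, config.H_c), rng)
    p["fp_b2"] = ad.zeros((config.H_c,))
    p["hf_W"] = ad.xavier_uniform((config.H_c, config.d), rng)
    p["hf_b"] = ad.zeros((config.d,))
    d = config.d
    for h in range(config.attn_heads):
        p[f"att{h}_Wv"] = ad.xavier_uniform((config.H_c, d), rng)
        p[f"att{h}_Wr"] = ad.xavier_uniform((config.H_p, d), rng)
        p[f"att{h}_U"] = ad.xavier_uniform((d, d), rng)
        p[f"att{h}_Wa2r"] = ad.xavier_uniform((d, d), rng)
        p[f"att{h}_Wr2a"] = ad.xavier_uniform((d, d), rng)
        p[f"att{h}_Wp"] = ad.xavier_uniform((d, d), rng)
        p[f"att{h}_Wc"] = ad.xavier_uniform((d, d), rng)
        p[f"att{h}_ar2a"] = ad.xavier_uniform((2 * d, 1), rng)
        p[f"att{h}_aa2r"] = ad.xavier_uniform((2 * d, 1), rng)
    p["merge_c_W"] = ad.xavier_uniform((config.attn_heads * d, d), rng)
    p["merge_c_b"] = ad.zeros((d,))
    p["merge_p_W"] = ad.xavier_uniform((config.attn_heads * d, d), rng)
    p["merge_p_b"] = ad.zeros((d,))
    widths = config.dense_widths()
    for layer, (win, wout) in enumerate(zip(widths[:-1], widths[1:])):
        p[f"dense{layer}_W"] = ad.xavier_uniform((win, wout), rng)
        p[f"dense{layer}_b"] = ad.zeros((wout,))
    return p


# -- encoder blocks -----------------------------------------------------------

def gat_encode(batch: Batch, params: dict[str, Tensor], config: ModelConfig,
               return_attention: bool = False):
    """Graph-attention encoding of atoms -> (B, Nv, H_c).

    Per head: standard GAT logits leakyReLU(a_src.Wh_i + a_dst.Wh_j) over
    each atom's neighborhood (self-loop included), softmax-normalized; the
    three head outputs (H_c' each) are concatenated and linearly projected
    to H_c with a leaky-ReLU activation.
    """
    slope = config.leaky_slope
    X = embedding(params["atom_emb"], batch.atom_tokens) * Tensor(batch.atom_mask)
    heads = []
    attns = []
    for h in range(config.gat_heads):
        Wh = X @ params[f"gat{h}_W"]                      # (B, Nv, H_c')
        src = Wh @ params[f"gat{h}_a_src"]                # (B, Nv, 1)
        dst = Wh @ params[f"gat{h}_a_dst"]                # (B, Nv, 1)
        logits = (src + dst.swapaxes(-1, -2)).leaky_relu(slope)  # (B, Nv, Nv)
        attn = masked_softmax(logits, mask=batch.adj, axis=-1)
        heads.append(attn @ Wh)
        if return_attention:
            attns.append(attn.data)
    V = concat(heads, axis=-1) @ params["gat_proj_W"] + params["gat_proj_b"]
    V = V.leaky_relu(slope) * Tensor(batch.atom_mask)
    if return_attention:
        return V, attns
    return V


def cnn_encode(batch: Batch, params: dict[str, Tensor],
               config: ModelConfig) -> Tensor:
    """Convolutional encoding of protein 3-mers -> (B, Nr, H_p).

    Same-padded 1-D convolutions implemented as sums of shifted linear
    maps, preserving one output row per 3-mer window.
    """
    slope = config.leaky_slope
    mask = Tensor(batch.res_mask)
    X = embedding(params["kmer_emb"], batch.kmer_tokens) * mask
    half = config.conv_kernel // 2
    for layer in range(config.conv_layers):
        out = None
        for o in range(-half, half + 1):
            term = shift(X, o, axis=1) @ params[f"conv{layer}_W{o}"]
            out = term if out is None else out + term
        X = (out + params[f"conv{layer}_b"]).leaky_relu(slope) * mask
    return X


def fingerprint_encode(fp: np.ndarray, params: dict[str, Tensor],
                       config: ModelConfig) -> Tensor:
    """MLP mapping a 1024-bit fingerprint batch to f in R^{H_c}."""
    fp = np.atleast_2d(fp)
    if fp.shape[-1] != 1024:
        raise ValueError(f"fingerprint must have 1024 bits, got {fp.shape[-1]}")
    h = (Tensor(fp) @ params["fp_W1"] + params["fp_b1"]).leaky_relu(config.leaky_slope)
    return h @ params["fp_W2"] + params["fp_b2"]


@dataclass
class AttentionOutput:
    """Final pair vectors plus per-head attention weights.

    alpha_a2r / alpha_r2a have shape (heads, B, Nv|Nr) and each valid slice
    is a probability simplex; A has shape (heads, B, Nv, Nr) with entries
    in [-1, 1] (range of tanh).
    """

    h_c_final: Tensor
    h_p_final: Tensor
    h_f: Tensor
    alpha_a2r: np.ndarray
    alpha_r2a: np.ndarray
    A: np.ndarray


def bidirectional_attention(V: Tensor, R: Tensor, f: Tensor, batch: Batch,
                            params: dict[str, Tensor],
                            config: ModelConfig) -> AttentionOutput:
    """Multi-head bidirectional atom<->residue attention.

    Per head: C = leakyReLU(V Wv), P = leakyReLU(R Wr); soft alignment
    A = tanh(C U P^T); residue direction I_p = A^T tanh(C W_a2r),
    alpha_r2a = softmax([P W_p || I_p] a_r2a); the atom direction mirrors it
    with I_c = A tanh(P W_r2a).  Head outputs are concatenated and projected
    back to d.
    """
    slope = config.leaky_slope
    amask = Tensor(batch.atom_mask)
    rmask = Tensor(batch.res_mask)
    hcs, hps, a2rs, r2as, As = [], [], [], [], []
    for h in range(config.attn_heads):
        C = (V @ params[f"att{h}_Wv"]).leaky_relu(slope) * amask   # (B,Nv,d)
        P = (R @ params[f"att{h}_Wr"]).leaky_relu(slope) * rmask   # (B,Nr,d)
        A = ((C @ params[f"att{h}_U"]) @ P.swapaxes(-1, -2)).tanh()  # (B,Nv,Nr)
        I_p = A.swapaxes(-1, -2) @ (C @ params[f"att{h}_Wa2r"]).tanh()  # (B,Nr,d)
        logit_r = concat([P @ params[f"att{h}_Wp"], I_p], axis=-1) @ params[f"att{h}_ar2a"]
        alpha_r2a = masked_softmax(logit_r.reshape(logit_r.shape[0], -1),
                                   mask=batch.res_mask[..., 0], axis=-1)  # (B,Nr)
        I_c = A @ (P @ params[f"att{h}_Wr2a"]).tanh()                 # (B,Nv,d)
        logit_c = concat([C @ params[f"att{h}_Wc"], I_c], axis=-1) @ params[f"att{h}_aa2r"]
        alpha_a2r = masked_softmax(logit_c.reshape(logit_c.shape[0], -1),
                                   mask=batch.atom_mask[..., 0], axis=-1)  # (B,Nv)
        h_p = (alpha_r2a.expand_last() * P).sum(axis=1)               # (B,d)
        h_c = (alpha_a2r.expand_last() * C).sum(axis=1)               # (B,d)
        hcs.append(h_c)
        hps.append(h_p)
        a2rs.append(alpha_a2r.data)
        r2as.append(alpha_r2a.data)
        As.append(A.data)
    h_c_final = concat(hcs, axis=-1) @ params["merge_c_W"] + params["merge_c_b"]
    h_p_final = concat(hps, axis=-1) @ params["merge_p_W"] + params["merge_p_b"]
    h_f = (f @ params["hf_W"] + params["hf_b"]).leaky_relu(slope)
    return AttentionOutput(h_c_final=h_c_final, h_p_final=h_p_final, h_f=h_f,
                           alpha_a2r=np.stack(a2rs), alpha_r2a=np.stack(r2as),
                           A=np.stack(As))


def forward(batch: Batch, params: dict[str, Tensor], config: ModelConfig,
            return_attention: bool = False):
    """Full forward pass -> predicted log10(kcat), shape (B,)."""
    V = gat_encode(batch, params, config)
    R = cnn_encode(batch, params, config)
    f = fingerprint_encode(batch.fp, params, config)
    att = bidirectional_attention(V, R, f, batch, params, config)
    z = concat([att.h_c_final, att.h_f, att.h_p_final, Tensor(batch.thermo)],
               axis=-1)
    n_dense = config.dense_layers
    for layer in range(n_dense):
        z = z @ params[f"dense{layer}_W"] + params[f"dense{layer}_b"]
        if layer < n_dense - 1:
            z = z.leaky_relu(config.leaky_slope)
    pred = z.reshape(batch.size)
    if return_attention:
        return pred, att
    return pred


# -- user-facing model object -------------------------------------------------

class KcatModel:
    """A trained (or freshly initialized) predictor bundling parameters,
    configuration, vocabularies and temperature-normalization stats."""

    def __init__(self, config: ModelConfig, atom_vocab: TokenVocab,
                 kmer_vocab: TokenVocab, stats: NormalizationStats | None = None,
                 params: dict[str, Tensor] | None = None):
        self.config = config
        self.atom_vocab = atom_vocab
        self.kmer_vocab = kmer_vocab
        self.stats = stats
        self.params = params if params is not None else init_params(
            config, len(atom_vocab), len(kmer_vocab))
        # embeddings are sized to the vocabularies at construction time;
        # later growth would index past the tables, so freeze them here
        self.atom_vocab.freeze()
        self.kmer_vocab.freeze()

    # featurization helpers ------------------------------------------------
    def featurize_one(self, smiles: str, sequence: str, t_celsius: float):
        if self.stats is None:
            raise RuntimeError("model has no fitted NormalizationStats; "
                               "fit on training temperatures first")
        g = smiles_to_graph(smiles, self.atom_vocab)
        t = protein_to_kmers(sequence, self.kmer_vocab)
        th = normalize_temperature(t_celsius, self.stats)
        return g, t, th

    def make_batch(self, rows) -> Batch:
        """rows: iterable of (smiles, sequence, temperature_C)."""
        gs, ts, ths = [], [], []
        for smiles, seq, tc in rows:
            g, t, th = self.featurize_one(smiles, seq, tc)
            gs.append(g)
            ts.append(t)
            ths.append(th)
        return collate(gs, ts, ths)

    def predict_batch(self, batch: Batch) -> np.ndarray:
        with ad.no_grad():
            return forward(batch, self.params, self.config).data

    def predict(self, rows, batch_size: int = 32) -> np.ndarray:
        """Predict log10(kcat) for (smiles, sequence, T_C) rows."""
        rows = list(rows)
        out = []
        for lo in range(0, len(rows), batch_size):
            out.append(self.predict_batch(self.make_batch(rows[lo:lo + batch_size])))
        return np.concatenate(out) if out else np.empty(0)

    def predict_single(self, smiles: str, sequence: str, t_celsius: float) -> float:
        return float(self.predict([(smiles, sequence, t_celsius)])[0])

    def attention_single(self, smiles: str, sequence: str,
                         t_celsius: float) -> AttentionOutput:
        batch = self.make_batch([(smiles, sequence, t_celsius)])
        with ad.no_grad():
            _, att = forward(batch, self.params, self.config, return_attention=True)
        return att

    # persistence ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "atom_vocab": self.atom_vocab.to_dict(),
            "kmer_vocab": self.kmer_vocab.to_dict(),
            "stats": self.stats.to_dict() if self.stats else None,
        }
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "KcatModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            config = ModelConfig(**meta["config"])
            params = {k: Tensor(npz[k], requires_grad=True)
                      for k in npz.files if k != "__meta__"}
        ref = init_params(config, len(meta["atom_vocab"]), len(meta["kmer_vocab"]))
        for k, t in ref.items():
            if k not in params or params[k].data.shape != t.data.shape:
                raise ValueError(f"checkpoint does not match config: parameter {k}")
        stats = (NormalizationStats.from_dict(meta["stats"])
                 if meta["stats"] else None)
        return cls(config,
                   TokenVocab.from_dict(meta["atom_vocab"], frozen=True),
                   TokenVocab.from_dict(meta["kmer_vocab"], frozen=True),
                   stats=stats, params=params)
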