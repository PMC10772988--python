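# thermokcat

Temperature-dependent prediction of enzyme turnover numbers (kcat), with
attention-based interpretation of the protein sequence and downstream
proteome-constrained flux balance analysis.

## The scientific problem

The turnover number kcat — how many substrate molecules one enzyme molecule
converts per second — is a strong function of temperature, yet most machine
learning predictors treat a (substrate, enzyme) pair as having a single
kcat. This package models the triple (substrate, enzyme, temperature):

* the **substrate** enters as a molecular graph (from its SMILES string) and
  a 1024-bit Morgan fingerprint,
* the **enzyme** enters as its amino-acid sequence, tokenized into
  overlapping 3-mers,
* the **temperature** enters as two scalar features, min–max normalized
  absolute temperature T and inverse temperature 1/T (the natural axis of
  Arrhenius kinetics).

The model predicts log10(kcat / s⁻¹).

## The model

* **Compound encoder** — a multi-head graph attention network (GAT) over
  atoms; attention is restricted to bonded neighbours plus a self-loop, so
  the encoding is equivariant to atom relabeling.
* **Protein encoder** — embedding of 3-mer tokens followed by a stack of
  same-padded 1-D convolutions with leaky-ReLU activations.
* **Bidirectional attention** — for each of several heads, projected atom
  and residue-window representations exchange information through an
  interaction matrix `A = tanh(C U Pᵀ)`; each direction produces a softmax
  distribution (atoms→residues and residues→atoms) that pools the other
  side. The residue-direction weights double as a per-residue importance
  profile for interpretation.
* **Regressor** — the pooled compound vector, a fingerprint embedding, the
  pooled protein vector and the two temperature features are concatenated
  and passed through a tapering dense stack.

Everything is implemented on a small reverse-mode automatic differentiation
engine over NumPy arrays included in the package (`thermokcat.autodiff`);
there is no deep-learning framework dependency.

Beyond prediction the package provides:

* **Interpretation** (`thermokcat.interpret`) — residue attention profiles,
  peak detection, annotation of experimental mutations against peaks, and
  in-silico mutant scans with fold-changes versus wild type.
* **Proteome-constrained FBA** (`thermokcat.proteome_fba`) — flux balance
  analysis (via COBRApy/GLPK) with a pooled proteome-sector constraint in
  which predicted kcat values set the enzyme cost of each catabolic flux, so
  temperature-dependent kcat curves translate into growth-versus-temperature
  curves.
* **Synthetic benchmark** (`thermokcat.synthetic_data`) — an Arrhenius
  kinetics generator whose ground-truth parameters are tied to sequence
  motifs and substrate composition, plus a small hand-solvable metabolic
  network; both are used throughout the test suite.

## Worked example

```python
import thermokcat as tk
from thermokcat.train import TrainConfig, evaluate

spec = tk.ArrheniusSpec(seed=7)               # 60 pairs x 6 temperatures
ds = tk.generate_arrhenius_dataset(spec)
train, val, test = tk.split(ds.entries, seed=7)
train = tk.oversample(train, seed=7)          # triple the T<20C / T>40C rows
model, history = tk.train_model(train, val,
                                tk.ModelConfig.small(seed=7),
                                TrainConfig(epochs=15, seed=7))

preds = model.predict([(e.smiles, e.sequence, e.temperature_C) for e in test])
m = evaluate(preds, [e.log10_kcat for e in test])
print(f"held-out: rmse={m.rmse:.3f}  mae={m.mae:.3f}  r2={m.r2:.3f}  (n={len(test)})")

e = test[0]
for t in (10.0, 25.0, 37.0, 50.0):
    print(f"  {t:4.0f} C  log10(kcat) = {model.predict_single(e.smiles, e.sequence, t):+.3f}")

gsmm, sectors, _ = tk.generate_toy_gsmm(seed=0)
print(f"plain FBA growth = {tk.fba(gsmm).growth:.2f}, "
      f"proteome-constrained = {tk.constrained_fba(gsmm, sectors).growth:.2f}")
```

Output (about 90 s on one CPU core):

```
held-out: rmse=0.255  mae=0.162  r2=0.992  (n=36)
    10 C  log10(kcat) = +2.622
    25 C  log10(kcat) = +2.978
    37 C  log10(kcat) = +3.223
    50 C  log10(kcat) = +3.426
plain FBA growth = 100.00, proteome-constrained = 19.63
```

The predicted temperature response is monotonically increasing and concave
on the log scale, as an Arrhenius law requires, and the proteome-sector
constraint cuts the toy network's growth from the exchange-limited optimum
to the enzyme-capacity-limited one.

The same workflow is available from the command line:

```sh
thermokcat simulate --pairs 60 --seed 7 --out kinetics.csv
thermokcat train --data kinetics.csv --small --epochs 15 --seed 7 --out model.npz
thermokcat eval --ckpt model.npz --data kinetics.csv
thermokcat interpret --ckpt model.npz --smiles CCO --sequence MKVL... --temp 37 --out profile.csv
thermokcat fba --model network.json --sectors sectors.json
```

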