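# Methods

This note records the model, the training and curation procedures, the
synthetic benchmark, the proteome-constrained FBA formulation, and the
numerical choices behind `thermokcat`, together with their assumptions and
limitations.

## 1. Inputs and featurization

* **Compound.** SMILES are parsed with RDKit. Each atom becomes a token
  keyed by `symbol | aromatic flag | degree`; bonds define an undirected
  adjacency to which self-loops are added. A 1024-bit Morgan fingerprint
  (radius 2) is computed per molecule. Unparsable SMILES raise
  `SmilesParseError` rather than being silently dropped.
* **Protein.** The sequence is tokenized into overlapping 3-mers
  (windows); a sequence of length L yields L−2 windows. Non-standard
  residues map to the shared unknown token. Token vocabularies are grown on
  the training set and frozen inside a model, so unseen tokens at
  prediction time map to `<unk>` instead of growing the embedding table.
* **Temperature.** Celsius inputs are converted to Kelvin
  (T_K = T_C + 273.15). Two features are used: T_K and 1/T_K, each min–max
  normalized with statistics fitted on the training set only. 1/T is
  included because log kcat is linear in 1/T under an Arrhenius law.
  Out-of-range temperatures are deliberately not clipped; extrapolation is
  allowed and its quality is the user's responsibility.

## 2. Architecture

All arrays are float64; the forward and backward passes run on a small
reverse-mode autodiff engine over NumPy included in the package. A deep
learning framework was not used because none is assumed present in the
target environment; the engine implements exactly the primitives the model
needs (matmul, leaky ReLU, tanh, masked softmax, embedding lookup with
scatter-add gradients, a zero-padded shift used to express same-padded
convolution, broadcast-aware reductions) and is validated by its own unit
tests against finite differences and hand-derived gradients.

* **GAT compound encoder.** Three heads; per-head width H_c′ projects the
  H_c-dimensional atom embeddings, attention logits use separate source and
  destination vectors with leaky-ReLU (slope 0.1), softmax is masked to
  bonded neighbours plus self. Head outputs are concatenated and linearly
  projected back to H_c. Padded rows keep a self-loop so their softmax is
  defined; their outputs are zeroed by the atom mask.
* **CNN protein encoder.** 3-mer embeddings of width H_p pass through
  `conv_layers` same-padded 1-D convolutions (kernel 3, leaky ReLU).
* **Fingerprint branch.** The Morgan fingerprint passes through a two-layer
  MLP to an H_c-dimensional vector h_f.
* **Bidirectional attention.** Per head: C = LReLU(V W_v),
  P = LReLU(R W_r), interaction A = tanh(C U Pᵀ); the residue direction
  scores `softmax([P W_p ‖ Aᵀ tanh(C W_a2r)] a_r2a)` and the atom direction
  mirrors it. Each direction's simplex weights pool the corresponding
  representation; heads are concatenated and projected to width d. Masked
  softmax guarantees padded positions receive exactly zero weight.
* **Regressor.** `[h_c_final ‖ h_f ‖ h_p_final ‖ T_norm ‖ (1/T)_norm]`
  (width 3d+2) feeds a dense stack whose widths taper geometrically to a
  single output, log10(kcat).

Default widths follow the full-size configuration (H_c=80, H_c′=50, three
GAT heads, H_p=80, four conv layers, d=64, three attention heads, four
dense layers). `ModelConfig.small()` (H_c=64, H_c′=32, H_p=64, two conv
layers, d=40, three dense layers) is this package's own compact setting,
chosen so that a full training run on the synthetic benchmark takes on the
order of a minute on one CPU core while leaving the architecture's
structure (multi-head GAT + CNN + bidirectional attention + temperature
features) intact.

## 3. Data curation and training

* **Deduplication** collapses entries sharing (smiles, sequence, T),
  keeping the largest kcat — the usual convention when assay conditions
  vary and the fastest measurement is closest to the enzyme's capability.
* **Splitting** is random by entry (`split`) or by compound–protein pair
  (`pair_disjoint_split`) for a stricter generalization estimate.
* **Oversampling** appends `factor` extra copies (default 2, i.e. tripling)
  of entries below 20 °C or above 40 °C, after splitting and only to the
  training set, to counteract the concentration of measurements near
  mesophilic temperatures. Validation and test sets are never resampled.
* **Optimization** minimizes mean squared error in log10(kcat) with Adam,
  batch size 32, initial learning rate 1e-3 halved every 10 epochs. The
  checkpoint with the best validation RMSE is kept. The benchmark runs in
  this repository use 15 epochs, which is where the small configuration's
  validation error plateaus on the synthetic benchmark; the schedule allows
  any epoch budget.
* **Metrics**: RMSE, MAE and R² on the log10 scale. R² is reported as NaN
  with a warning when the evaluation targets have zero variance.

## 4. Temperature-importance diagnostic

`permute_temperature_importance` shuffles the (T, 1/T) feature pair jointly
across an evaluation set (keeping compound/protein fixed) and compares RMSE
over repeated permutations with the unshuffled RMSE. A median shuffled RMSE
above baseline indicates the model actually uses the temperature channel
rather than memorizing pair identities.

## 5. Interpretation

The residue-direction attention weights α_r2a are read out per head over
3-mer windows; window j (0-based) is reported at its center residue, the
1-based position j+2. Peaks are strict local maxima (plateaus report their
leftmost index; an all-equal profile has no peaks). Experimental mutations
are annotated with the distance from their position to the nearest peak
(ties to the lower position); a mutation is called *severe* when its
measured fold-change is below 0.1, and `fraction_severe_near_peak` uses a
window of 10 residues. In-silico mutant scans apply substitution specs such
as `Y227C/E277G` (validated against the wild-type sequence) and report
predicted fold-changes versus wild type at chosen temperatures.

## 6. Proteome-constrained FBA

Plain FBA maximizes the objective flux subject to Sv = 0 and bounds, via
COBRApy with the GLPK solver. The proteome constraint adds a single pooled
sector budget:

v_growth/a_rib + Σ_catabolic m_i·|v_i| + v_AT/a_AT + v_CT/a_CT ≤ (1−φ_Q)·P_TOT

with φ_Q = 0.5 (non-metabolic proteome fraction), P_TOT = 0.5 g protein /
g dry weight, ribosome specific activity a_rib = 107.4 (mmol h⁻¹ g⁻¹
scale), transporter activities a_AT = 6360 and a_CT = 361.14. A catabolic
reaction's mass cost per unit flux is m = (MW/1000) / (kcat·3600) when a
turnover number and molecular weight (g/mol) are given, or 1/(a·60) for a
specific activity in µmol min⁻¹ mg⁻¹. Reversible reactions are split into
forward and reverse variables so enzyme capacity is consumed in both
directions. Predicted kcat values enter through `kcat_overrides` or the
`growth_vs_temperature` table (one kcat per reaction per temperature),
turning temperature-dependent turnover into growth-versus-temperature
curves. When several isozymes or substrates are predicted for one reaction,
`select_reaction_kcat` takes the maximum over isozymes and a named (or
first-listed) primary substrate.

Assumptions: a single pooled budget rather than per-enzyme abundance
constraints; full saturation of every enzyme (flux = kcat·E upper bound);
constant MW and activities across temperature.

## 7. Synthetic benchmark

`generate_arrhenius_dataset` draws compound–protein pairs (SMILES from a
fixed template list, random sequences of length 50–300) and assigns each a
ground-truth Arrhenius law log10 kcat(T) = logA − Ea/(R·T·ln10) with

* logA in [6, 12], increasing linearly with the count of three fixed
  sequence motifs (AKR, WND, CYH), plus small Gaussian jitter — so the
  protein branch has real signal to find;
* Ea in [20, 80] kJ/mol tied to the substrate's oxygen count — so the
  compound branch controls the temperature slope;
* observation noise of σ = 0.1 in log10 units, multiplicative in kcat.

Defaults (60 pairs, temperatures 10/20/25/30/37/50 °C, σ = 0.1) are the
study conditions used by the test suite and the acceptance script. The
generator emulates the *structure* of the learning problem — sequence- and
substrate-dependent kinetic parameters with an exact Arrhenius temperature
law and lognormal noise. It does not emulate real kcat distributions,
enzyme families, denaturation above the optimum temperature (curvature
beyond Arrhenius), or measurement-condition confounders; results on it
bound implementation correctness and learnability, not real-world accuracy.
`inject_mutation_effects` adds point-mutated variants whose logA is shifted
by a known amount, for exercising the mutant-scan workflow against ground
truth. `generate_toy_gsmm` builds a 7-reaction metabolic network whose
plain and proteome-constrained optima have closed-form solutions used as
oracles.

## 8. Numerical choices

* float64 throughout; no mixed precision.
* Softmax subtracts the row maximum before exponentiation; fully masked
  rows are given a uniform distribution over the (absent) support and then
  zeroed, so padding can never produce NaN.
* Xavier-uniform initialization for weight matrices, zeros for biases;
  every run is fully determined by integer seeds (NumPy `default_rng`).
* Checkpoints are NumPy `.npz` archives with a JSON metadata block
  (config, vocabularies, normalization statistics, format version); loading
  validates every array shape against the config and fails loudly on
  mismatch.
* LP tolerances are GLPK defaults; tests compare against closed forms at
  1e-6.

## 9. Limitations

* No real measured kcat data ship with the package; all quantitative
  results in the tests and acceptance script are on synthetic data
  (`scripts/full_training_run.py` exists for user-supplied real datasets).
* The NumPy engine is single-threaded per operation and has no GPU path;
  full-width training on large datasets is correspondingly slow.
* Above-optimum temperature behaviour (denaturation) is outside both the
  model's inductive bias and the generator.
* The pooled single-budget proteome constraint is the simplest member of
  the enzyme-constrained FBA family; it ignores enzyme abundance data and
  per-sector budgets.
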