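# Methods

## Model

`glcndta` predicts drug–target binding affinity (DTA) as a regression
task from two graphs per example:

* **molecule graph** — heavy atoms as nodes, covalent bonds as edges,
  self-loops on every node; each atom carries a 78-dimensional binary
  feature vector (44-slot element one-hot with a catch-all slot, 11-slot
  one-hots for degree, total-H and implicit-H counts clamped at 10, and
  an aromaticity flag);
* **protein graph** — residues as nodes; the adjacency is a predicted
  residue–residue contact-probability matrix, max-symmetrized and
  thresholded at 0.5 (inclusive), with forced self-loops; each residue
  carries a 54-dimensional vector (21-slot residue one-hot incl. the
  unknown class 'X', a 21-column PSSM row, five chemical-group flags,
  and min–max-normalized mass, pKa(-COOH), pKa(-NH₃), side-chain pKx,
  pI and hydrophobicity at pH 2 / pH 7).

Each branch is a *graph learning-convolutional network* (GLCN).  Raw
features are first linearly projected to `d_model`.  A layer then:

1. **learns a soft adjacency** A: `e_ij = LeakyReLU(wᵀ |v_i − v_j|)`,
   `A_i = softmax(e_i)` — every row is nonnegative and sums to one.  The
   softmax support is all node pairs: the learned matrix *replaces* the
   fixed bond/contact adjacency during convolution (the fixed adjacency
   is retained in the data model, and `graph_learning(..., allowed=...)`
   can restrict the support to it for ablation);
2. **accumulates the graph-learning regularizer**
   `L_GL = (1/N²) Σ_ij exp(A_ij + η ‖v_i − v_j‖²) + γ ‖A‖²_F`,
   differentiable in both A and the node features;
3. **computes pairwise hidden features** `h_ij = relu(W_vih v_i + W_vjh v_j + b)`;
4. **convolves** `v_i′ = relu((Σ_j A_ij h_ij) W)` — row i of A acts as
   convex-combination weights over node i's hidden vectors.

After `n_layers` (default 2) layers, a graph-level vector is read out by
coordinatewise max pooling (mean pooling available).  The drug and
protein vectors are concatenated (2·`d_model`), passed through two fully
connected layers — LeakyReLU after the first only, dropout after each —
and a final linear unit yields the affinity.

The training objective is `L_total = L_dta + λ·L_GL`, with `L_dta` the
batch mean squared error and `L_GL` the per-layer regularizers of both
branches summed, averaged over the mini-batch.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `d_model` | 128 | embedding width of both branches |
| `n_layers` | 2 | GLCN depth per branch |
| `eta` (η) | 1 | distance weight inside the regularizer's exponential |
| `gamma` (γ) | 1 | Frobenius-norm trade-off of the regularizer |
| `lambda_gl` (λ) | 1 | weight of `L_GL` in the joint objective |
| `fc_dims` | (1024, 512) | widths of the two FC head layers |
| `dropout` | 0.2 | dropout after each FC layer (never after the output) |
| `lr` | 5·10⁻⁴ | initial Adam learning rate |
| warmup | 10 epochs | linear learning-rate warmup from 0 |
| decay | ×0.8 every 40 epochs | step decay after warmup |
| `batch_size` | 128 | examples per Adam step |
| `epochs` | 1000 | full training schedule |

Affinities are modelled on the pKd scale (`−log₁₀(Kd/10⁹)`, Kd in nM) or
any comparable activity score (e.g. KIBA); a loader flag applies the pKd
transform to raw Kd matrices.

Design choices made where the architecture description is open:

* the graph-learning weight `w` is one shared vector per layer, not one
  per node — per-node weights could not transfer across graphs of
  different sizes;
* the head widths (1024, 512) follow the sizes common in comparable DTA
  regressors and are fully configurable;
* "warm" learning-rate setting is implemented as a 10-epoch linear
  warmup;
* LeakyReLU negative slope 0.01 everywhere it appears;
* parameter initialization is uniform Glorot, fully seed-controlled;
* λ defaults to 1.  Note an internal tension in the published ablation
  of this architecture family: the λ-sweep table shows its best MSE at
  λ = 0.5 while the accompanying text calls λ = 1 optimal; we keep 1 as
  the documented default and expose the flag.
* Minimizing `γ‖A‖²_F` over row-stochastic matrices actually favours
  *uniform* rows rather than sparse ones; the term is implemented
  exactly as defined and no sparsity property is asserted or relied on.

## Gradients and numerics

No GPU autodiff framework is used: the package ships a small
reverse-mode tape (`glcndta.autodiff`) over float64 numpy arrays.  The
two O(N²·d_model) bottlenecks — the pairwise |·|-distance statistic of
graph learning and the pairwise convolution — run through fused,
numba-compiled kernels that never materialize the N×N×d stack on the
tape; the composed reference operations (`pairwise_hidden`,
`graph_conv`, …) remain the public API, and the test suite pins the
fused path to them at ~1e-15 and to central finite differences at
<1e-3 relative error end-to-end (<1e-4 for the regularizer alone).

Other numerical choices:

* masked softmax excludes padded columns and zeroes padded rows, so the
  Frobenius and exponential terms see only real nodes; mixed-size
  padded batches reproduce per-graph execution to <1e-6;
* the exponent of the regularizer is masked *before* `exp` so padded
  distances cannot overflow;
* pairwise squared distances use the Gram-matrix identity with a clamp
  at zero against floating-point negatives; max-pooling routes tied
  gradients to the first maximum;
* inside a mini-batch, gradients are accumulated over micro-chunks
  (default 16 pairs, grouped by protein length) purely to bound memory;
  the chunked sums are mathematically identical to full-batch execution;
* contact maps are validated to [0, 1] and symmetrized with the
  elementwise maximum before thresholding; the 0.5 comparison is
  inclusive (`≥`);
* the concordance index enumerates all ordered pairs with strictly
  different true affinities (O(n²)); true-value ties are excluded from
  the normalizer and prediction ties earn 0.5;
* r²m uses the standard through-origin slope `k = Σyŷ / Σŷ²` and
  `r₀² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²`, with the radicand clamped at 0.

## Synthetic data

Real DTA benchmarks require external downloads plus alignment-derived
contact maps and PSSMs, so the package ships a generator that emulates
the full input contract at desk scale:

* **drugs** — sampled without replacement from a frozen library of 153
  curated drug-like SMILES (8–40 heavy atoms, rdkit-validated, spanning
  common pharmacophores);
* **proteins** — uniform-random sequences over the 20 canonical
  residues, default length 30–60 (compact single-domain scale chosen so
  the full pipeline runs in minutes on one core); banded contact maps
  (probabilities in [0.8, 1] within |i−j| ≤ 2, long-range contacts at
  rate 0.05 drawn from [0.6, 1], background in [0, 0.4)); PSSM rows from
  a symmetric Dirichlet (concentration 0.5, giving peaked,
  conserved-looking rows);
* **affinities** — a planted linear function of interpretable entity
  statistics (drug heavy-atom count and aromatic fraction, protein
  contact density and hydrophobic fraction; weights 1.0/0.7/0.8/0.6 on
  min–max-scaled statistics) rescaled into the Davis-like pKd range
  [5, 11], plus Gaussian noise (default σ = 0.3; 0 for the noise-free
  overfitting fixture).

The generator writes a complete DeepDTA-style benchmark directory
(ligand/protein JSON tables, dense affinity matrix, per-protein
`.cmap`/`.pssm` files, fold JSONs) that round-trips losslessly through
the loader, byte-identically for a fixed seed.

What the synthetic data does **not** emulate: real secondary-structure
contact topology, evolutionary covariation in PSSMs, chemotype-specific
binding (the planted function is additive in drug and protein
statistics, with no interaction term), and benchmark-scale sample sizes.
Passing the learning-capacity check therefore demonstrates that the
architecture, gradients and training loop work end to end — it does not
certify accuracy on real Davis/KIBA-scale data, which would require the
external inputs listed above and the full 1000-epoch schedule.

## Problem sizes used in tests and the acceptance script

The learning-capacity check trains the *default* model (2 layers,
d_model 128, FC 1024/512, dropout 0.2, λ = η = γ = 1) on 50 noise-free
pairs (10 drugs × 5 proteins) for 300 epochs, ~3 minutes on one core,
and verifies evaluation-mode training MSE < 0.05 and CI > 0.9.
Structural checks (feature widths, soft-adjacency row sums over random
graphs, oracle equivalence on small instances, finite-difference
gradient agreement, batching contract, determinism, checkpoint round
trips) use graphs of 1–20 nodes and complete in seconds.

## Known limitations

* Contact-map prediction and alignment pipelines are out of scope;
  contact maps and PSSMs are inputs.  `pseudo_pssm` (smoothed one-hot)
  is an explicit sequence-only fallback, not a substitute for
  alignment-derived profiles.  Any real-valued N×21 matrix is accepted
  as a PSSM (probability- or log-odds-scaled).
* The regularizer's `exp(η‖v_i − v_j‖²)` can overflow if embeddings
  drift far apart early in training; the trainer aborts with a
  diagnostic on non-finite loss rather than silently clipping.
* Training is CPU-bound numpy/numba; benchmark-scale runs (10⁵ pairs,
  1000 epochs) are out of reach of this implementation and out of scope.
* The model predicts a single affinity scalar; it does not localize
  binding sites or distinguish ordered from intrinsically disordered
  proteins.
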