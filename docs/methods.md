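# Methods

This note documents the models implemented in `mapent`, the assumptions they
make, the numerical choices behind them, and what the synthetic fixtures do
and do not demonstrate.

## Mapping entropy

A decimation mapping `M` keeps `N` of the `n` heavy atoms of a molecule.  The
information lost by observing the system only through `M` is the mapping
entropy,

    S_map = k_B * D_KL( p_r || pbar_r ),

the Kullback–Leibler divergence between the microscopic Boltzmann
distribution `p_r` and the distribution `pbar_r` obtained by spreading each
coarse-grained macrostate's probability uniformly back over its microstates:
`pbar_r(r) = p_R(M(r)) / Omega_1(M(r))`, where `Omega_1(R)` counts the
microstates mapping onto `R`.  `S_map >= 0`, with equality when the mapping
discards nothing (identity partition) or when the distribution is uniform
within every macrostate.

Two estimators are provided:

* **Exact discrete** (`exact_smap_discrete`) — direct summation over the
  microstates of a finite system.  Used as the ground truth in all tests.
  Returns values in units of `k_B`; multiply by `k_B = 0.0083145 kJ/mol/K`
  for thermal units.
* **Variance-based** (`estimate_smap`) — for sampled ensembles, a
  second-order cumulant expansion of the KL divergence reduces `S_map` to a
  weighted average over macrostates of the within-macrostate variance of the
  atomistic potential energy.  The prefactor in `cumulant` mode is
  `k_B * beta^2 / 2`; the exact constant of the expansion is not fixed by the
  procedure this package follows, so a `unit` mode exposes the bare weighted
  variance for structural testing.  The within-macrostate variance is the
  *population* variance weighted by frame counts (or by explicit per-frame
  weights for exact-weight ensembles), which matches the weighted-average
  reading most directly; a sample-variance variant would differ only at
  O(1/frames).  Consistency between the two estimators is verified in the
  vanishing-fluctuation limit, where the relative error of the cumulant
  estimate against `k_B x KL` decreases monotonically with the energy spread.

Macrostates of a continuous ensemble are identified by single-linkage
grouping of frames with the max-per-atom Euclidean distance over retained
atoms; the tolerance is a required parameter (0 demands exact coordinate
equality).  The grouping rule is a package choice: the underlying theory
defines macrostates through the mapping itself, and any finite-sample
grouping is a numerical surrogate for that definition.

## Contact graph

Each heavy atom of one protein chain is a vertex with 10 binary features:
one-hot element (C/N/O/S), one-hot residue class, a backbone flag (atom name
in {N, CA, C, O}), and the Site flag marking retained atoms.  Undirected
edges connect atoms closer than 1 nm (strict inequality), weighted by the
inverse distance in nm^-1.  The graph is built once from a single reference
conformation; mappings only rewrite the Site column.

The residue-class table assigns the 20 standard amino acids to hydrophobic
{ALA, VAL, LEU, ILE, PRO, PHE, MET, GLY}, amphipathic {TRP, TYR, THR}, polar
{SER, CYS, ASN, GLN, HIS} and charged {ASP, GLU, LYS, ARG}, a standard
hydropathy grouping kept as a single constant (`RESIDUE_CLASSES`) so that an
alternative assignment can be swapped in.  Non-standard residues and heavy
elements outside {C, N, O, S} are rejected rather than silently defaulted.

Average degree is reported as directed (ordered-pair) edges per vertex with
integer truncation; stored edges are unique unordered pairs.  Alternate
locations keep the highest-occupancy copy; the first model and first protein
chain are used unless a chain is named.  Coincident atoms are an error — an
infinite edge weight has no physical reading.

## Graph-network surrogate

The surrogate is a graph isomorphism network with scalar edge weights:

* layer 1: `h^1_v = ReLU(W_e x_v + b_e)`, `x_v` the 10 features;
* layers 2..L: `h^{l+1}_v = ReLU(W_l [(1+eps_l) h^l_v + sum_u h^l_u e_uv] + b_l)`
  with one adaptive scalar `eps_l` per convolution;
* readout: each vertex's L states are concatenated (length `K*L`), scaled by
  a scalar `w_s` for retained vertices and `w_n` otherwise, summed over
  vertices and projected with `w_out` (length `K*L`) plus an output bias.

Excluding biases the trainable count is
`10K + K^2(L-1) + KL + (L-1) + 2`, i.e. 17,350 at the reference size K=64,
L=5.  Defaults: MAE loss, Adam at learning rate 0.001 with no weight decay,
mini-batches of 8, an 80/10/10 hold-out split, early stopping on the
validation MAE with the best-epoch weights returned.  A `mean` readout
variant (plain vertex-state average) exists behind `readout_mode`; the
weighted-sum readout is canonical because it reproduces the weight census.
Targets are trained in kJ/mol/K; `normalize_targets` optionally standardizes
them during fitting (predictions are always de-standardized) and defaults
off.

The implementation is plain NumPy — forward, hand-derived backward (verified
against central differences to ~1e-9 relative error) and Adam — in float32,
with every random draw taken from one seeded generator so that two runs with
the same seed produce bitwise-identical epoch logs.

Three parameterization choices matter and are deliberate:

* All weight arrays are initialized with a symmetric fan-in-scaled uniform
  scheme and *live at unit scale*; the convolution layers apply an explicit
  gain `1 / (1 + 2*sum(e_uv)/n)` — the inverse of the graph's mean total
  edge weight per vertex — inside the forward pass (`gain * W_l`).  The
  edge-weighted neighbour sum multiplies activation magnitude by roughly
  that factor per layer, so without the gain the activations inflate by
  several orders of magnitude before the first update; folding the gain into
  the *initialization scale* instead is function-equivalent at epoch 0 but
  leaves parameters three orders of magnitude smaller than the optimizer's
  uniform step size, and training then merely churns them.  The explicit
  gain keeps both the activations and the optimizer geometry well scaled,
  and on the synthetic benchmark it is the difference between a stalled fit
  and an essentially exact one.
* `w_s = 1, w_n = 0`: the readout starts as a sum over retained vertices
  only.  Starting from `w_s = w_n` places the bilinear readout on a slow
  symmetric manifold, and the all-vertex sum carries a large common-mode
  component that drowns the informative gradient under the sign-valued MAE
  gradients; both effects measurably stall training.
* The output bias is initialized to the training-target mean, so training
  starts from the predict-the-mean baseline rather than spending its first
  epochs discovering the offset through sign gradients.

## Simulated annealing

Moves swap one retained with one non-retained atom (symmetric proposal,
Hamming distance 2, fixed N); acceptance is Metropolis,
`min{1, exp(-(S'-S)/T(i))}`, under the exponential schedule
`T(i) = T0 exp(-i/v)`.  `T` absorbs the oracle's units.  When not supplied,
`T0` defaults to the oracle's score spread over 100 random mappings and `v`
to `steps/5`; both resolved values are recorded on the result.  The best
mapping and a non-increasing best-score trace are tracked.  Four preset run
lengths (20000, 10000, 5000, 2500 steps) mirror the grouping used for
optimized dataset entries.

## Wang–Landau sampling

The density of states `Omega_N(S)` counts mappings per score bin of width
`delta_s` (default 0.2) inside a window `[s_min, s_max]`.  The walk works in
log space `Sigma = ln Omega`: a proposed swap with an in-window score is
accepted with `min{1, exp(Sigma[current] - Sigma[proposed])}`; out-of-window
proposals are rejected; every move (accepted or not) adds `ln f` to the
resulting current bin and increments its histogram count.  When every
ever-visited bin's count lies strictly within `(p_flat, 2 - p_flat)` times
the mean (default `p_flat = 0.8`), the histogram resets and `ln f` halves;
the run stops when `ln f < ln f_end` (defaults `ln f_0 = 1`,
`ln f_end = 1e-6`, hence exactly 20 halvings).  `Sigma` starts at 0
everywhere (`Omega = 1`) and is defined up to an additive constant;
never-visited bins are reported as `-inf` and excluded from flatness, since
a discrete score spectrum can leave unreachable bins inside the window.
Numerical conversion to bin probabilities uses a log-sum-exp shift.

Decisions the scheme leaves open, fixed here: flatness is checked every
1,000 moves (`check_interval`); bins are half-open with the top edge closed;
the initial in-window mapping is found by uniform random draws with a 10^5
budget.

### Validation against exhaustive enumeration

On toy spaces small enough to enumerate (120 and 495 mappings), the
converged `Sigma`, shifted to match the exact `ln`(counts) at the modal bin,
agrees with an RMS error well below 0.2 ln-units over occupied bins.  The
WL-derived bin probabilities are also compared with the empirical histogram
of 10^6 uniformly drawn mappings; the agreement band is three combined
standard errors, combining the binomial error of the histogram with the
across-replica standard error of four independent WL chains.  The replica
term matters: at 10^6 draws the binomial error (~1e-3) is smaller than the
intrinsic WL accuracy, which is set by the modification-factor floor and the
noise frozen in during early iterations, so a purely binomial band would
measure WL chain noise rather than agreement.

## Synthetic fixtures

`make_toy_structure` grows a self-avoiding chain of pseudo-residues (0.38 nm
step, 1–8 heavy atoms each, 0.05 nm minimum separation) with backbone atom
names N/CA/C/O and standard residue names, so every structure passes the
full featurization path.  `ToyOracle` scores a mapping as
`a * (sum of edge weights among retained atoms) + b * |retained backbone|
+ c * hash-noise`, sharing the graph's inverse-distance structure so that at
`c = 0` the landscape is smooth and representable by the surrogate — making
desk-scale training a meaningful analogue of the real regression task —
while large `c` makes it unlearnable.  Defaults a = b = 1, c = 0.
`make_discrete_ensemble` encodes macrostate and microstate identity in two
atoms' coordinates so that `assign_macrostates` at tolerance 0 provably
recovers the generating partition.

What the fixtures do **not** emulate: real protein energetics, conformational
ensembles, or the MD-derived mapping-entropy labels of real proteins.
Passing tests demonstrate the correctness of the estimators, samplers and
learning machinery — not that a surrogate trained on these fixtures would
predict the mapping entropy of an actual protein.

## Problem sizes used in the checks

The shipped verification runs are sized for a single CPU: surrogate
learnability uses a ~100-atom structure, 3,000 labeled mappings (85% random,
15% annealed with run lengths 2000/1000/500/250), hidden width K = 32,
at most 500 epochs with patience 100, reaching test R^2 >= 0.9; the
permuted-label control runs 150 epochs with patience 75, where any epoch
count leaves R^2 near 0.  Wang–Landau validation uses mapping spaces of 120
and 495 elements with full-range windows.  These sizes are the package's
choices for self-contained verification; the architecture itself defaults to
the reference size K = 64, L = 5.

## Known limitations

* The surrogate is protein-specific by construction: a model trained on one
  graph does not transfer to another molecule.
* The cumulant-mode prefactor is the package's reading of the second-order
  expansion; deviations beyond second order are not estimated.
* Single-linkage macrostate grouping is sensitive to the tolerance; there is
  deliberately no default.
* The Wang–Landau implementation is the classic halving scheme; no 1/t
  refinement or multi-window stitching is provided.
* PDB parsing handles standard single-chain protein ATOM records; mmCIF,
  nucleic acids, ligands and multi-chain graphs are out of scope.
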