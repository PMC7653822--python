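# Methods

## Problem setting

Given an aligned enzyme family (equal-length sequences over the 21-symbol
alphabet of 20 amino acids plus the gap `-`, which is treated as an
ordinary symbol everywhere) and a per-sequence optimal-condition label such
as optimal pH, the package learns which symbols at which alignment sites
push the optimum up or down, ranks sequences by a predicted optimal
condition, and proposes substitutions that shift a wild type toward an
expected condition.

## Partition and site selection

Labeled sequences are split at a threshold into a high-condition set S_h
(label strictly greater than the threshold) and a low-condition set S_l
(label at or below it). The default threshold is pH 7; `"mean"` uses the
label average instead. A boundary label goes to S_l.

Each site's usefulness is measured by the information gain of its column
about the high/low class: Gain(k) = H(y) − H(y|k), the plug-in mutual
information of the 2×21 class-by-symbol contingency table, computed without
smoothing and clipped at zero against floating-point rounding. Entropies
default to base 2 (bits); the base is configurable, and the selection
threshold ω is only meaningful relative to a base, so users matching an ω
from elsewhere must match the base too. Sites with Gain(k) ≥ ω (inclusive
boundary; default ω = 0.0478) form the *selected* set; the rest are
conserved or uninformative and are excluded from training, scoring and
mutation. Note that the plug-in estimator is positively biased at small n —
on a 96-sequence training split a completely uninformative column with an
effective alphabet of ~9 symbols has an expected spurious gain near
(R−1)(C−1)/(2N ln 2) ≈ 0.06 bits — so at family sizes around 100 the
selected set includes background sites as well; this costs score variance
but not bias, since background columns look alike in both classes.

## Embedding model and training objective

Every site k has a vector v_k ∈ R^d and every symbol a a vector c_a ∈ R^d
(symbol vectors are shared across sites; d defaults to 30). Two scores are
read off the table:

- capability score s(k, a) = v_k · c_a;
- suitability score s(n_i, n_j) = (v_i ⊕ c_i) · (v_j ⊕ c_j)
  = v_i·v_j + c_i·c_j for two occupied sites of the same sequence.

A softmax over the full event space would need an intractable normalizer;
noise-contrastive estimation replaces it with a learnable scalar, one per
objective (C for single events, C_pair for pairs, both initialized to 0),
and trains by logistic discrimination of data events against noise events:

    L = −[log σ(Δ⁺) + log(1 − σ(Δ⁻))],   Δ = (s + C) − log p_n,

averaged over the batch, with the two objectives blended as
α·L_T + (1−α)·L_C (α default 0.4). Positive single events are (site,
symbol) occurrences drawn uniformly from S_h sequences at selected sites;
positive pair events take two distinct selected sites from one S_h
sequence. The noise distribution p_n is uniform over selected sites times a
per-site symbol categorical fitted on S_l with additive smoothing 1e-3
(pair noise factorizes over the two sites; ordered distinct site pairs);
a uniform noise model is available as an option. One noise sample per
positive is drawn by default. This S_l-based noise makes "data vs noise"
coincide with "high vs low condition": as training converges, s(k, a) + C
approaches log p_n(k, a) plus the log-density ratio of high-class to
low-class events, so the capability chart becomes a per-site log-likelihood
ratio between the classes.

Gradients are analytic (the positive-sample site gradient is
−(1−σ(Δ⁺))·c_a for the single objective and −(1−σ(Δ⁺))·v_j for the pair
objective; noise samples contribute with coefficient +σ(Δ⁻)), verified
against central finite differences to <1e-5 relative error in the test
suite. Optimization uses Adam (lr 0.01, β₁ 0.9, β₂ 0.999, ε 1e-8) on
mini-batches of 32 positives, with all randomness flowing through one
`numpy` generator seeded from the config — training is bit-reproducible
single-threaded. The step limit defaults to 20,000 with an early stop when
the mean loss over successive 500-step windows changes by less than 1e-4
relative; the tests and the acceptance script run 3,000 steps, which on the
synthetic families used there is past the point where the windowed loss and
the downstream accuracy stop moving. Initialization is zero-mean Gaussian
with σ = 0.1. A NaN loss aborts with a diagnostic rather than returning a
corrupt table.

## Approximation method (augmentation)

Families with on the order of 100 labeled members are small for embedding
training. The package therefore fits per-class, per-site symbol frequency
profiles on the training split and samples pseudo-sequences from them
site-independently (inverse-CDF per column), appending `augment_factor`
(default 10) times each class's size before training. Pseudo-sequences
inherit only the class membership of their source profile, never a numeric
label. Site-independent sampling preserves the per-site marginals — the
only statistic the downstream objective consumes through the noise model
and single events — but deliberately destroys inter-site linkage, so the
pair objective sees weaker real covariation as the augmentation factor
grows. The fidelity of the approximation is quantified by the per-site KL
divergence between a training subset's column distributions and the full
family's (additive pseudocount 1e-6 inside KL only, to tolerate empty
cells); `kl_curve` reproduces the experiment of sampling training
proportions 50–90% and shows the divergence shrinking as the proportion
grows.

## Quantitative score, ranking and evaluation

    Score(a) = α · Σ_{k∈sel} s(k, a_k) + (1−α) · Σ_{i<j∈sel} s(n_i, n_j) / l

Both sums run over selected sites only (configurable to all sites); the
pair sum uses unordered distinct pairs and keeps the 1/l normalization even
though the pair count is not l — only relative scores matter for ranking.
Two sequences are compared by Score (absolute difference below 1e-9 is a
tie). Ranking accuracy judges all unordered test pairs with distinct
labels: a pair is correct when the score order matches the label order;
equal-label pairs are excluded and ties count as incorrect.
`cross_validate` runs repeated stratified random splits (default 8:2, 10
repeats), recomputing gains and the selected set on each training split so
no information leaks from the test side.

## Mutation suggestion

Eligible sites must carry a non-gap wild-type symbol (edits must preserve
the alignment length) and gain ≥ ω. Single-site search scores every
(site, symbol) substitution exhaustively via incremental score deltas —
for an edit at site k the single term changes by α·v_k·(c_new − c_old) and
the pair term by (1−α)/l·(c_new − c_old)·(Σ_{j∈sel} c_{a_j} − c_{a_k});
multi-site combinations add a pairwise interaction term
(1−α)/l·d_p·d_q between edited sites. Combinations of up to 3 sites are
searched exhaustively when the candidate set has ≤15 sites and greedily
(best remaining single edit while the score improves) otherwise; both modes
can be forced. The gap is never a target symbol. Ties prefer fewer edits,
then the lexicographically smallest (site, symbol). A suggestion is
returned only when it strictly improves the score. A raised score predicts
a shift of the optimum in the expected direction, not a guaranteed activity
gain — the score carries no structural feasibility information.

## Synthetic families

`generate_synthetic_family` emulates the statistical structure of a real
labeled family: a minority of *planted* sites where the high-condition
class prefers the alkali-resistant residues Lys/Arg with probability
`effect` (acidic Asp/Glu otherwise) and the low class the mirror image,
all other sites sharing one background distribution — uniform over the
eight common residues A, G, S, T, N, Q, V, L with 5% gap mass, a realistic
effective alphabet for variable MSA columns that also exercises gap
handling. Labels are uniform on (7.5, 9.5) for the high class and
(4.5, 6.5) for the low class. Defaults: 120 sequences, length 60, 8 planted
sites, effect 0.9, balanced classes.

What the generator does *not* emulate: phylogenetic correlation between
sequences, inter-site linkage beyond the planted signal, and — important
for interpreting ranking numbers — any within-class association between a
sequence and its numeric label: labels are drawn independently of the
residues given the class. Consequently same-class test pairs are
intrinsically unorderable (expected accuracy 0.5), which caps the expected
overall pairwise accuracy on a balanced family at roughly 0.74 even for a
perfect scorer; cross-class accuracy is the informative quantity on these
fixtures (the trained model reaches ~1.0 there), and passing tests say
nothing about within-class ordering on real families, where labels do
covary with sequence.

## Numerical choices and limitations

- log σ terms use `logaddexp`; losses are finite for any finite scores.
- Information gain uses no smoothing; KL uses pseudocount 1e-6; the NCE
  noise model uses 1e-3 — three different roles, deliberately decoupled.
- Site indices are 1-based at every user-facing surface; the mutation
  notation "D56R" uses aligned-site numbering.
- Ambiguous residue codes (X, B, Z, U, ...) are rejected by default;
  `ambiguous="gap"` maps them to the gap symbol.
- The model table serializes to a plain TSV bundle with `repr` floats and
  round-trips exactly.
- Scores are family-specific: a table trained on one alignment is
  meaningless for columns of another alignment.
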