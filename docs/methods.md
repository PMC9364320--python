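# Methods

## Embedding model

Molecules are mapped to points in a D-dimensional real space such that
fingerprint distance is preserved as Euclidean distance as far as the data
allow.  The pipeline is landmark MDS: L landmark molecules are projected by
classic (Torgerson) scaling of their L×L distance matrix, and every other
molecule is placed by triangulation from its distances to the landmarks
alone.  Two assumptions underlie this: (i) the fingerprint/similarity
combination captures the structural variation relevant to the property being
modelled, and (ii) the landmark set spans the chemical subspace of interest
(hence L ≫ D; defaults L = 50, D = 15).

Fingerprint distances are generally *not* Euclidean-realizable, so the
double-centered matrix B = −½ J D² J has negative eigenvalues.  We keep the
top-D eigendirections and zero out coordinates along any direction whose
eigenvalue is non-positive or below 1e−9 of the leading eigenvalue.  The
relative cutoff matters numerically: the triangulation operator divides by
√λ, and directions with vanishing λ would amplify rounding noise ­— with the
cutoff, a landmark's own distance row reproduces its stored coordinates to
~1e−12.  Eigenvector signs are fixed (largest-magnitude entry positive) and
columns ordered by descending eigenvalue, so embeddings are bit-reproducible
across runs.

Similarity is converted to distance as d = 1 − s.  This is the bounded,
zero-at-identity choice (Soergel distance for Tanimoto, where it is a true
metric); the conversion is a single replaceable function so alternatives
such as √(1−s) are a one-line change.  Two metric-specific decisions:
McConnaughey similarity natively spans [−1, 1] and is affinely rescaled to
[0, 1] (identity still maps to 1); "blay-roger" is registered as a name but
raises until a user supplies a formula, since no published definition is
available.  All-zero fingerprints (featureless molecules under sparse
fingerprint types) are defined as similarity 1 to another all-zero vector
and 0 to anything else, which keeps distances bounded without 0/0.

Landmark selection modes: `random` (uniform without replacement, default),
`binned` (equal-width property bins; each draw picks a non-exhausted bin
uniformly, then a member uniformly — sparse property ranges get equal
representation, which helps skewed datasets), `highest`/`lowest` (extremes
by property value).  The alternative projections (`pca`, `ica`, `fa`) are
fit on the landmarks' distance-to-landmark row vectors and applied to query
distance rows; `isomap` replaces landmark distances with geodesics over a
k-nearest-neighbour graph (k = 5) before classic MDS and routes query
distances through the nearest landmark.  All preserve the O(N·L) transform
cost, which the embedder instruments with an exact distance-computation
counter.

## Automatic hyperparameter recommendation

`macaw_optimus` scores each (fingerprint, metric) candidate by the mean
k-fold CV R² of an RBF-SVM (C = 100, ε = 0.1, fixed at selection time; the
final model is tuned separately) on the candidate's embedding.  Landmark
indices, seed and fold assignments are shared across candidates, so the
comparison is paired.  The default grid is 9 fingerprints × 5 metrics — a
deliberate desk-scale subset; the full 14 × 11 grid is available by passing
the complete registries.  Ties break by lower score sd, then grid order.

## Robust token-string generation

The generator requires a molecular string representation in which any token
sequence decodes to a valid molecule.  `macaw.tokenstrings` implements one:
atom tokens with bond-order prefixes (`[C]`, `[=O]`, …), branch delimiters,
and relative ring-closure tokens (`[Ring5]`), decoded under hard-coded
valence caps (C 4, N 3, O 2, S 2, P 3, halogens 1, B 3, Si 4).  The decoder
clips bond orders to the free valence on both ends, skips unrealisable
branch/ring instructions, and reattaches to the most recent open atom when
the current one saturates — so decoding cannot fail, and only a sequence
with no realisable atom token yields no molecule.  Encoding is a
deterministic DFS (kekulized, stereo dropped); round-trips are exact and
property-tested.  Molecules outside the neutral organic subset (charges,
isotopes, hypervalent centres) are rejected at encoding with a listed error.

Probability matrices follow three factorizations of token frequency:
`position` (token × position), `transition` (previous token × next token,
with a virtual begin-of-string row), `dual` (both).  `position` is the
constructor default; the evolver calls the generator with `transition`,
which conditions each token on its predecessor and in practice keeps local
chemistry of the seeds.  Counts are normalized row-wise and blended with the
uniform matrix: row′ = (1−η)·normalize(row) + η·uniform, all-zero rows
mapping to uniform at any η.  At η = 1 every sampling row is exactly
uniform; at η = 0 sampling is confined to observed tokens.  The default
noise_factor is 0.3 — enough diversity to escape the seed set without losing
its chemistry; the inverse-design acceptance measurement uses 0.5.

String lengths are drawn from p(n) ∝ exp(βn) truncated at max_len (the
longest encoded input by default; 20 in no-input mode).  β = +1 as printed —
this concentrates mass near max_len — with β exposed in the API because a
negative rate is the physically common alternative.  The no-input mode uses
a fixed predefined alphabet (C/N/O/F atoms at common bond orders, branch
delimiters, ring sizes 3–6).  Library assembly deduplicates by canonical
SMILES only (no tautomer or stereo merging) and bounds the rejection loop at
20·n draws so a tiny alphabet terminates with a warning rather than hanging.

## Hit search

The V-distance d_V(v₁,v₂) = Σᵢ p^{i−1}·sort↑(|v₁−v₂|)ᵢ (0 < p ≤ 1) weights
the *smallest* per-dimension deviations most, so a molecule far away in one
dimension but close in the rest is penalized less than under Euclidean
distance; p = 1 recovers Manhattan exactly.  It violates the triangle
inequality in general, so k-NN queries under it bypass the ball tree and use
an exact vectorized scan — correctness over speed; Minkowski orders p ≥ 1
use a BallTree.  `hit_finder` seeds the search with the k1 training
molecules whose measured property is nearest the target and predicts only
the ≤ k1·k2 deduplicated neighbours.  `hit_finder_grad` minimizes
(model(x) − target)² by L-BFGS-B with numerical gradients from k1 random
library points; non-converged restarts are dropped, and if all fail the
start points themselves seed the neighbour lookup.

## Directed evolution

Defaults k1 = 3000 generated per round, k2 = 100 carried over, 8 rounds,
10 hits returned.  Each round refits the generator's probability matrix on
the current k2 selection only — this is what progressively focuses
generation — with noise_factor held constant.  Carried-over molecules keep
their stored predictions (the embedding is static within a run), duplicates
resolve by canonical SMILES keeping the earlier prediction, and the
selection pool always contains the previous round's selection, which makes
the best |prediction − target| non-increasing by construction.  Model
evaluations are bounded by k1·n_rounds + k2.

## Model evaluation and feature informativeness

`nested_cv_svr` performs 10-fold outer CV; within each outer training
partition a 5-fold grid search tunes (C, ε) over {1, 10, 100, 1000} ×
{0.1, 0.5, 1, 5}, the best setting is refit on the full partition, and the
held-out fold is predicted.  Pooled metrics are computed from the
out-of-fold predictions, which form an exact partition of the data.
Feature construction can be made fold-aware through an `embed_fn` callback
(retrain the embedder per fold), so validation molecules never influence
the embedding; the convenience mode with a precomputed feature matrix is
available but documented as leaky for embedder-derived features.

Mutual information uses the k-nearest-neighbour continuous estimator
(k = 3, scikit-learn's `mutual_info_regression`), reported in nats;
constant features return 0 by definition.  The estimator is validated
against the bivariate-Gaussian closed form −½ln(1−ρ²) in the tests.
`mi_heatmap` equalizes sample sizes across datasets by subsampling before
comparing MI magnitudes.

## Synthetic study sets and the surrogate property

The synthetic generator builds molecules grammatically — random carbon
trees of bounded size (≤ 20 heavy atoms) decorated per family (linear
alkanes, branched alkanes, alcohols, alkenes, monoaromatics) — so validity
is guaranteed by construction and every set is reproducible from its seed.
The surrogate property is

    y = 60 + 8·branch points + 10·unsaturations + 15·oxygens − 3·heavy atoms

(+ optional Gaussian noise), which yields an octane-rating-like scale
(~5–85 over the default mix) with the canonical trend directions: long
unbranched saturated chains score low; short, branched, unsaturated,
oxygenated molecules score high.  Branch points are carbons with ≥ 3 carbon
neighbours; unsaturations are non-single bonds after kekulization.

What the synthetic sets do *not* emulate: real structure–property maps are
not linear in substructure counts, real datasets carry measurement noise
and uneven chemical coverage, and the families span a narrow slice of
chemistry (no charges, no stereochemistry, few heteroatoms).  Passing tests
therefore demonstrate that the machinery is correct and that the pipeline
can recover a recoverable signal — not that any particular real property
will be predicted with the same accuracy.

## Problem sizes and numerical choices

The test suite and acceptance checks run at desk scale by design: study
sets of 500 molecules, L = 50, D = 15, evolver runs of k1 = 300 / k2 = 50 /
8 rounds, 10,000-sample generator validity measurements, and 5,000-point
k-NN libraries.  Degenerate inputs are handled explicitly: constant
targets report NaN R² with a warning; constant features have zero MI;
all-zero probability rows sample uniformly; oversized k1 clips with a
warning.  Ties in evolver selection break by canonical-SMILES lexicographic
order; k-NN ties break by index order.  Exact-equality contracts (setter
truncation, V-distance vs Manhattan) are asserted up to floating-point
summation order (≤ 1e−12) where BLAS blocking differs between shapes.

## Known limitations

Binary fingerprints only (no counts, no 3D); the token grammar covers the
neutral organic subset and rejects charged, isotopic or hypervalent
molecules; `fit_transform` reuses train-time landmarks rather than
re-selecting; the evolver seeds each round's generator with the current
selection only; no uncertainty-aware acquisition — composite objectives are
supported by wrapping them in the property-model contract.
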