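# Methods

## Sequence representation

Each protein is encoded residue-by-residue with the three-component Hellberg
z-scales, principal-component summaries of 29 physicochemical amino-acid
properties: z1 is dominated by hydrophobicity, z2 by molecular size, z3 by
polarity. The 20 × 3 table ships as `src/allerknn/data/hellberg_z3.tsv`; its
header records the transcription source and the independent reproductions it
was checked against. The values are dimensionless descriptor units.

Input handling: sequences are uppercased and stripped of whitespace before
validation (plain pasted text round-trips). Strict mode (the default)
rejects any character outside the 20 standard one-letter codes, naming the
position and character; permissive mode substitutes averaged descriptor
triples for ambiguity codes (B → mean of D,N; Z → mean of E,Q; J → mean of
I,L; X/U/O → column-wise mean of all 20 residues) and warns. Strict is the
default because silent substitution distorts the covariance terms without
any visible trace in the output.

## ACC transformation

Auto-covariance terms A_jj(l) and cross-covariance terms C_jk(l) are means
of lagged descriptor products over positions i = 1…n−l, for lags l = 1…L
with L = 5 by default (only close residue proximity is modelled). Both
orders of each cross pair (C_12 and C_21) are kept — the sequence is
directional — giving 3² × 5 = 45 features. The layout is frozen and
identified as `acc-z3-pairmajor-v1`: pair-major, lag-minor, in the order
(A11, A22, A33, C12, C13, C21, C23, C31, C32) × l = 1…5, with column names
`A11_l1 … C32_l5`. Any fixed order is statistically equivalent; the
identifier is written into every serialized model and checked on load so
vectors and models can never silently disagree about feature order.

The minimum sequence length is L + 1 = 6, the shortest length for which
every lag has at least one summand; shorter queries are rejected per record
with an explicit message.

Numerically, the lagged sums can cancel to values orders of magnitude below
the individual products, so each term is computed from float64 element-wise
products accumulated and averaged in extended (80-bit) precision and rounded
once back to float64. This keeps the production transform within ~1e-15
relative of an exact-summation evaluation of the same formula, and makes the
homopolymer identities A_jj(l) = z_j², C_jk(l) = z_j·z_k hold bit-exactly.

## Classification

k-nearest neighbours over the 45-dimensional vectors. Defaults reproduce
the method's published operating point: k = 3, decision threshold 0.5.
Design choices where the method description is open:

- **Distance**: Euclidean (standard for ACC/QSAR feature spaces);
  Manhattan is available as a config option to make the assumption
  explicit and testable.
- **Scaling**: off by default (raw ACC values); optional per-feature
  z-score standardization is fitted on the training fold only. Zero-variance
  features are excluded from the standardized space with a warning. Both
  modes are exposed because the choice measurably changes neighbourhoods.
- **Score and verdict**: the score is the allergen fraction among the k
  neighbours (a multiple of 1/k); verdict is allergen iff score ≥
  threshold. The score is rankable, which is what makes AUC meaningful for
  this classifier; neighbours are not distance-weighted.
- **k parity**: k is restricted to odd values so the 0.5 threshold can
  never land on a 50/50 vote; the k-scan runs over odd k only.
- **Ties**: equal distances are broken by training-set insertion order
  (stable sort), making predictions fully deterministic.

Route of exposure: among the allergen-labelled neighbours each route tag
counts once per neighbour carrying it (multi-route allergens vote for every
tag); highest count wins, ties go to the route of the nearest allergen
neighbour, then to the fixed order food < inhalant < toxin. If an allergen
verdict is reached with no allergen neighbour (possible only when the
threshold is lowered below 0.5), the route is reported as absent with a
warning.

Models serialize to a versioned flat JSON file (format id, feature-layout
id, k, metric, scaling parameters, instances). Serialization is
deterministic: identical data and settings give byte-identical files.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
F1 = 2·sens·ppv/(sens+ppv), all at the decision threshold (default 0.5).
(Source descriptions of this family of methods sometimes misprint the
specificity formula as FP/(TN+FP), which is the false-positive rate; the
TN/(TN+FP) form used here is the quantity those descriptions actually
report.) Metrics undefined on the given data — e.g. sensitivity of a
single-class sample, or PPV when nothing is predicted positive — are
reported as NaN with a warning, never silently as zero.

AUC uses the Mann–Whitney rank formulation with average ranks, so
between-class score ties earn half credit. The rank form (rather than
trapezoidal integration over an arbitrary threshold grid) matters here
because kNN scores are coarse multiples of 1/k and tie-heavy.

Cross-validation is stratified 5-fold (80/20). All fold-dependent fitting —
standardization parameters and the model itself — uses the training fold
only. Fold results are aggregated by pooling confusion counts
(micro-average); per-fold reports and a per-fold macro-average are kept
alongside. The k-scan computes the folds once and reuses them for every k,
so per-k differences are paired, not resampling noise. No monotone trend in
k is asserted anywhere: small non-monotone drifts are expected.

The route cross-comparison trains one model per route dataset (food,
inhalant, toxin, and their pooled total) and scores every model on every
route's test folds. Diagonal cells are honest held-out estimates (model of
fold f scored on its own route's test fold f); off-diagonal cells score the
same per-fold models on another route's test folds, so no model ever sees
its own test data.

## Mirror non-allergen sets

For each allergen one non-allergen candidate of the same species is drawn
(reproducibly from a seed) subject to a dissimilarity screen; when the
species pool is exhausted the cascade falls back to the genus (first token
of the species tag) and then to a designated fallback pool, and a remaining
shortfall is an error, never a silent smaller set. The default screen
rejects any candidate sharing an exact 8-mer with any allergen — the 6–8
contiguous-residue identity window used in allergenicity guidelines
motivates the word size — and an optional adapter shells out to NCBI
`blastp` (reject on any hit at E-value ≤ 0.001) when the binaries are on
PATH. The exact BLAST parameterisation used in the original protocol
(program, matrix, word size) is not recoverable, which is a known
limitation; both screens are config-selectable and logged.

## Synthetic data generator

The generator emulates the shape of curated allergen collections so every
stage of the pipeline is testable without downloading any database: two
classes of iid-residue sequences whose compositions differ, lengths uniform
on 50–300 residues, 300 proteins per class by default, route proportions
29/48/23 % (food/inhalant/toxin, the approximate mix of public allergen
collections) with an 8 % chance of a second route per allergen, and species
tags cycling over a small pool.

Class separation is produced by composition bias along the descriptor axes.
The default allergen class doubles the frequencies of I, L, V and F
(renormalised) — echoing the allergen-specific surface-exposed hydrophobic
patches reported for real allergens — which moves the class along z1 and
measurably shifts the z1 auto-covariances. For the route cross-comparison,
each route's allergens are displaced along a different axis using disjoint
residue groups: food I/L/V/F (z1), inhalant W/Y/R/H (z2), toxin C/P (z3;
cysteine/proline-rich, echoing disulfide-dense venom toxins). Two design
points required care because ACC features are approximately quadratic in
the mean descriptor vector (A_jk(l) ≈ m_j·m_k for iid residues):

- groups containing D or N would push z1 strongly positive and, after
  squaring, alias with the z1-negative hydrophobic axis — hence the polar
  group is C/P only;
- a fixed mixing weight displaces rare-residue groups less than common
  ones, so the mixture weight is instead derived from a target centroid
  displacement (1.4 z-units from background for every route), making the
  three route classes comparably separable by construction.

What the generator does **not** emulate: residue order structure
(sequences are iid given composition, so there are no motifs, domains,
repeats or disulfide patterns), homology within and between classes,
database redundancy, label noise, and class overlap as it occurs in curated
data. Passing the recovery tests therefore shows that the pipeline
faithfully detects composition-driven physicochemical class structure — the
signal the ACC representation is built to expose — not that it attains any
particular accuracy on real allergen collections, whose published headline
figures required the original compiled datasets.

Generation is reproducible: all randomness flows from the single seed in
the spec; identical specs produce byte-identical datasets.

## Problem sizes

Default study conditions are 300 proteins per class for cross-validation
and the k-scan, and 100 per class per route for the cross-comparison grid;
the full test suite and the reproduction script run in well under a minute
on one core at these sizes.

## Known limitations

- Whether the original server standardized features before the neighbour
  search, weighted neighbour votes by distance, or how its AUC score was
  defined, is not documented; the choices above (raw features, unweighted
  votes, allergen-fraction score) are explicit and config-visible.
- The kNN score takes only k+1 distinct values, so ROC curves are coarse.
- Strict-mode validation excludes proteins with ambiguity codes from
  training sets (they are flagged, counted and reported, not dropped
  silently); permissive mode trades that safety for coverage.
- Only the 3-component z-scale descriptor set is implemented; other
  descriptor families (z5, VHSE, ProtFP) would be extensions of the
  encoding step, and nucleotide input is out of scope.
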