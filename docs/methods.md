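# Methods

This note documents the models and procedures implemented in `labbgc`, the
assumptions behind them, the parameters that matter, and the design choices
made where the procedure left room.

## Family and clan clustering

BGCs are represented by nonnegative biosynthetic-domain weight vectors; the
package consumes these vectors (TSV) and does not extract them. Cosine
distance is the metric throughout, which makes the partition invariant to
positive rescaling of any vector — only domain *composition* matters.
All-zero ("featureless") vectors have no direction; they are rejected by the
distance computation, stripped before clustering, and carried through reports
as unassigned rather than dropped silently.

Clustering is agglomerative with average linkage on the full distance
matrix. One tree serves both cuts: families at merge height `< 0.2`, clans at
`< 0.8`, so the family partition refines the clan partition by construction.
The cut is strict; scipy's flat-cut criterion is `<=`, so the tree is cut at
the largest float below the threshold (`nextafter(t, 0)`), which makes a
merge at exactly the threshold split. With continuous distances, linkage ties
have probability zero; the test oracle (an independent greedy agglomerator)
breaks hypothetical ties toward lexicographically smallest member indices.

Reference ("known-like") annotation: each BGC's distance to the reference
set is the minimum cosine distance over reference vectors after projecting
both matrices onto the union domain vocabulary (absent domains are zero). A
clan aggregates member values by arithmetic mean and is flagged known-like
below 0.2. Mean-of-min was chosen over min-of-mean: the per-BGC minimum is
the natural "nearest characterized neighbour" notion and the clan mean
summarizes how much of the clan sits near known chemistry.

Taxa-specificity labels are cumulative — a single-species family is also
single-genus, and a strain-singleton (one member BGC) is both — matching how
overlapping percentages are conventionally reported for such tables;
`cross_genus` flags ≥ 2 genera.

## Presence and abundance in samples

Only biosynthetic-related genes (gene_kind `biosynthetic` = core, and
`biosynthetic-additional`) participate; transporters, regulators and other
accessory genes are excluded from both the presence criterion and the
abundance sum. A gene counts as *detected* at mapped-read count ≥ 1 — the
weakest reading consistent with the criterion, and the only one monotone in
sequencing depth. "Over 50%" is strict (`> 0.5`): 2 detected of 4 related
genes is absent. A BGC with no core gene cannot satisfy criterion (2) and is
reported *uncallable* (boolean NA in the presence matrix plus an explicit
list), never silently absent.

Abundance is the mean per-gene length-normalized read rate, scaled by the
library size: `(Σ N_i/L_i) / (k·N) × 10⁶`. It is invariant under joint
scaling of all counts and N, halves when every gene length doubles, and is
zero iff all counts are zero, so presence implies positive abundance. Both
raw and presence-masked abundance matrices are emitted, since figures may
want either convention. Metatranscriptomes use the same formulas with N the
non-rRNA, non-host read total.

Dereplication before quantification is greedy and longest-first within each
family: a sequence joins the best (highest-identity) existing representative
at global nucleotide identity ≥ 0.8 relative to the shorter sequence,
otherwise founds one. Identity relative to the shorter sequence is the
simplest auditable definition; best-fit rather than first-fit joining keeps
the rule deterministic and order-independent given the length sort.
Identical sequences in different families are deliberately *not* merged —
the family is the quantification unit.

Accumulation curves permute sample order (default 100 permutations, seeded)
and report mean ± sd of the running distinct-family count; the endpoint
equals the site's union cardinality for every permutation. Niche-specificity
(detected in exactly one site) crosses with taxa-specificity into 2×2 tables
for chi-squared testing.

## Precursor analysis

Detector hit sets are unioned with provenance preserved; sequences > 150 aa
are discarded (class II precursors are short; longer ORFs are likely
mispredictions). Clustering is greedy incremental, longest-first, at 50%
identity with a 0.95 length-ratio guard and 0.95 coverage of the longer
sequence — the accurate-mode variant (best representative, ties to the
longer one) of the standard word-based tool's criteria. The word-filter
heuristics themselves are *not* emulated: at the scales this package
targets, exact global alignments are affordable and are the criterion the
heuristics approximate. Two identity denominators coexist deliberately:
clustering uses identical positions / shorter-sequence length (the
clustering tool's convention), while reported global identity uses identical
positions / alignment length (the global-aligner convention). Peptide
alignments score BLOSUM62 with gap open 10 / extend 0.5, end gaps penalized
in global mode; these defaults are declared in `AlignmentConfig`, not
asserted to match any external tool.

Known-bacteriocin matching is local (Smith–Waterman, same scoring) with the
known sequence as query: a member is homologous at identity > 0.90 over the
aligned columns and > 0.95 of the query's residues aligned; a cluster is
known-like when any member is homologous, labelled by the best-identity
known sequence. Curated known bacteriocins are often mature (leader-cleaved)
peptides, which is why matching is local with query-side coverage.

## Ecology statistics

Shannon diversity uses natural log (nats) over renormalized nonzero entries.
Spearman rho is the Pearson correlation of mid-ranks with the two-sided
t-approximation p-value (the behaviour of the common correlation routines at
these sample sizes); |rho| = 1 maps to p = 0, and constant vectors yield a
missing value with a warning rather than an arbitrary number. BH adjustment
is standard step-up. The network screen computes all cluster × species and
cluster × Shannon correlations with a vectorized rank/t path (cross-checked
against the scalar routine in the tests), adjusts the two test families
separately — they carry different rho cutoffs (−0.3 species, −0.4 Shannon)
and separate adjustment matches their separate reporting — and emits the
full edge list, rejected pairs flagged, plus a GraphML export of the
retained graph. Chi-squared on 2×2 tables is Pearson's without continuity
correction by default (the intended comparisons have large counts; a flag
enables it).

## Bioactivity evaluation

The evaluation protocol, not any particular classifier, is the reproducible
content: learners are a contract (declared hyperparameter space, `fit`,
real-valued `decision_scores`), with a regularized logistic scorer and a
randomized tree ensemble shipped as references. Feature filtering (present
in ≥ 10 BGCs) is fit inside each outer training split and merely applied to
the held-out fold; the leakage guard in the tests verifies that corrupting
test-fold labels leaves the fitted models bit-identical under fixed folds.
Outer folds are stratified — required for rare activity classes — which the
protocol's source did not state. AUROC is trapezoidal over tied score
groups, equal to the Mann–Whitney pair-counting estimate with ties counted
half. A `--repeats` flag repeats the whole nested procedure with shifted
seeds rather than guessing how multiple instances per classifier should
arise.

## Synthetic data: what it emulates, and what it does not

The generators produce the pipeline's *inputs* with planted truth; they do
not simulate reads, trimming, host removal, or realistic domain names.

- **Features**: each planted family owns a disjoint block of domains with
  prototype weights U(0.5, 1.5); members perturb a fraction
  `within_family_noise` of *background* (non-prototype) entries with small
  weights U(0.05, 0.25). This models variable accessory domain content with
  conserved class-defining domains, and keeps families cosine-separable for
  any noise fraction < 0.5 (higher is rejected loudly). Real feature
  variance also touches the defining domains; recovery on this generator
  therefore shows correctness of the clustering chain, not robustness to
  adversarial feature noise.
- **Counts**: presence is Bernoulli(0.5) per (sample, BGC); present BGCs
  emit Poisson counts with mean `read_depth · a · L/1000` per gene
  (lognormal per-pair factor `a`), so the length-normalized estimator is
  exact in expectation. The library size N is drawn first, an order of
  magnitude above the expected emitted total (N in real data counts the
  whole metagenome, which the generator does not model), and reported with
  the table.
- **Precursors**: each cluster derives from one random seed peptide
  (30–100 aa) by per-position substitutions at `mutation_rate`, uniform
  over the 19 other canonical residues. Identity to the representative is
  (1 − rate) in expectation, so the cluster invariant holds for any
  rate < 0.25; exact recovery is guaranteed (and asserted) at rate ≤ 0.1.
- **Community**: species profiles are row-normalized lognormals; planted
  negative edges make a cluster's abundance a strictly decreasing affine
  function of its species' abundance plus Gaussian noise
  (`community_noise · sd`), giving rho = −1 exactly at zero noise.
- **Detector hits**: id sets of prescribed sizes/overlap with a prescribed
  number of oversize (> 150 aa) members — pure bookkeeping for the
  merge/filter stage.

Two presets fix the study conditions for validation: **easy** (defaults:
8 families × 6 BGCs over 120 domains, noise 0.05; 80 samples, depth 30;
8 precursor clusters × 6 at mutation rate 0.05; 8 species, 3 planted edges,
community noise 0.15) is the regime under which all recovery guarantees are
asserted; **hard** (noise 0.35, mutation 0.2, depth 4, community noise 0.6)
stresses the same stages and carries no guarantee. The easy/hard settings
are package conventions — nothing in the underlying study characterizes
within-family feature variance — so passing recovery tests demonstrates the
pipeline's correctness on well-posed inputs, not performance on real data.
Problem sizes throughout (dozens of BGCs/precursors, tens of samples,
hundreds of null replicates) were chosen as the smallest that exercise every
code path and give the statistical assertions comfortable margins.

One global seed drives everything; sub-generators derive fixed child streams
from it (`numpy` SeedSequence spawn keys), so any generator can be called
alone or as part of the full bundle with identical output.

## Numerical choices and degenerate inputs

- Cosine distances are clipped to [0, 1] against floating-point drift; the
  diagonal is forced to zero.
- Spearman rho within 1e-12 of ±1 snaps to ±1 so the perfect-monotone
  contract (p = 0) holds despite rank-arithmetic rounding.
- Distance matrices are validated (square, symmetric to 1e-12, nonnegative,
  zero diagonal) before clustering; asymmetry is an error, not averaged away.
- Empty reference sets, all-zero abundance rows, constant correlation
  inputs, single-class label vectors, zero library sizes and zero margins
  all raise with specific messages rather than propagating NaNs.

## Known limitations

- Exact-alignment clustering is quadratic in the number of sequences per
  comparison set; it is meant for desk-scale analyses (10²–10³ precursors),
  not the full-repository scale where word-filter heuristics earn their keep.
- The presence criterion's "detected" threshold (count ≥ 1) has no coverage
  notion; shallow contamination can flip short genes.
- The association screen is correlational; compositional effects of
  relative-abundance profiles are not modelled beyond what rank statistics
  absorb.
- Reference learners are deliberately small; the protocol accepts external
  learners but ships no tuned search spaces for them.
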