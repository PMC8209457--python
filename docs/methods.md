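# Methods

This note records the models, numerical conventions, and design choices
behind `beetscreen`, in the spirit of the methods documentation of the
larger simulation and statistics packages.

## Distances

Input alignments are preconditions: rows of equal length over
`{A,C,G,T,U,N,-,.}` (U is read as T). Two models are offered. The
p-distance (mismatches / comparable columns) carries the screen's
"97% identity" semantics directly, so the OTU threshold of 0.03 is
interpreted on the p scale throughout the pipeline. The Jukes–Cantor
correction d = −¾ ln(1 − 4p/3) is provided because the classic
PHYLIP-era distance tools default to it; JC distances are slightly larger
than p, so clustering JC distances at the same cutoff yields slightly
coarser OTUs. Columns where either row carries a gap or N are dropped per
pair (pairwise deletion): this matches the behaviour of those tools,
keeps distances defined for ragged ends, and treats N conservatively as
missing rather than as a mismatch. p ≥ 0.75 makes the JC logarithm
undefined; the package raises a distinct `JCSaturationError` rather than
clamping, because silently saturated distances would corrupt clustering.
The all-pairs routine computes match counts with one-hot matrix products
(exact for counts below 2²⁴, far above any alignment length used here)
and is asserted against the per-pair loop in the tests.

## OTU clustering

Furthest-neighbour (complete-linkage) agglomeration with a stop rule:
merging ends when the smallest inter-cluster linkage distance exceeds the
threshold. Furthest linkage is the default because it guarantees the
property the identity threshold is meant to express — no two sequences
within an OTU differ by more than the cutoff — and because it was the
default of the era's clustering tools; the tool actually used by the
original survey is not recorded, so this is an assumption, and nearest /
average linkage are available for sensitivity analysis. Ties are broken
by (smaller linkage distance, then lexicographically smallest member-id
pair), and OTU labels are assigned by descending size then smallest
member id, so output is reproducible across platforms. The implementation
keeps a cached row-minimum structure (O(n²) typical) and is verified
against an exhaustive greedy oracle on small random instances.

## Alpha diversity

The survey names its indices without formulas; the conventions adopted
are those of the era's standard clone-library toolkit, and are fixed and
documented rather than configurable:

* Good's coverage Cx = 1 − n₁/N (n₁ singletons, N library size).
* Chao1, bias-corrected: S_obs + n₁(n₁−1)/(2(n₂+1)).
* ACE with rare/abundant split at 10, C_ACE = 1 − F₁/N_rare, and the
  squared coefficient of variation clamped at zero; when every rare OTU
  is a singleton (C_ACE = 0) the estimator is undefined and S_obs is
  returned with a warning.
* Shannon H′ in natural log; unbiased inverse Simpson
  1/D, D = Σ nᵢ(nᵢ−1)/(N(N−1)) (N ≥ 2; all-singleton vectors make D = 0
  and are signalled).

For reproducing printed one-decimal tables the package rounds
half-away-from-zero (`round_half_away`), matching the printed style.
Printed Chao1/ACE values in the survey's summary table cannot be
recomputed without the unpublished full abundance distributions; they are
consistency-checked on synthetic data only, whereas the coverage row is
an exact identity in the printed N and n₁ and is recomputed directly.

## Trees and ordination

Neighbor joining follows the standard Q-matrix formulation with
vectorised candidate selection, deterministic tie-breaking on leaf
labels, and negative branch-length estimates clamped to zero (standard
practice; UniFrac requires non-negative lengths). On additive matrices
the patristic distances of the result reproduce the input to 1e-9
(property-tested against random tree metrics, and cross-checked against
an independent NJ implementation). Bootstrap support resamples alignment
columns with replacement and reports, per internal edge of the
point-estimate tree, the fraction of replicate trees containing the same
bipartition.

Weighted UniFrac between relative-abundance profiles A and B is
Σᵢ bᵢ·|Aᵢ−Bᵢ| over branches, where Aᵢ is the fraction of community A
descending from branch i. Because only "abundance-weighted" is specified
by the survey, both the raw and the normalised
(÷ Σᵢ bᵢ·(Aᵢ+Bᵢ)) variants are first-class; raw is the default and the
acceptance checks run both. Unrooted trees are midpoint-rooted before the
branch sweep (a root is required; the choice is documented and the
rooting preserves tip-to-tip distances).

PCoA is classical metric scaling: B = −½·J·D²·J, eigendecomposition,
coordinates = eigenvectors × √λ over positive eigenvalues. Negative
eigenvalues are reported but excluded from coordinates and from the
variance fractions; no Lingoes/Cailliez correction is applied
(documented simplification). Axis signs follow the convention that the
largest-magnitude loading is positive. The ordination percentages of the
original survey's figure (PC1 44.5%, PC2 26.0%) depend on its external
alignment and tree and are not treated as reproducible; the structural
claim — the leading axis separates above- from below-ground libraries —
is what the package asserts, on affinity-separated synthetic studies
(20/20 seeds, both UniFrac variants). In those checks the tree is drawn
from an arbitrary random tree metric over the OTUs, which makes the
assertion stronger: the separation is carried by the abundance structure,
not by a particular phylogeny.

## Composition and the two-library comparison

Sequences count toward their rank taxon when the classifier confidence
reaches 0.8, else toward "unclassified <deepest confident parent>"
(sub-threshold labels roll up rather than being dropped, so columns
always sum to 100%). Frequency differences between two libraries use an
exact Poisson-ratio comparison: with counts x, y from libraries of sizes
N_x, N_y and r = N_y/N_x, the point probability is
P(y|x) = rʸ(x+y)!/(x! y! (1+r)^(x+y+1)); tails are summed in log space
and the two-sided p doubles the smaller tail, capped at 1. The cited
legacy comparison program's exact statistic is unpublished, so this form
is a documented stand-in. Tail-doubling of this conditional form is not
perfectly symmetric under exchanging the libraries (the underlying
negative-binomial/binomial tail identity shifts the trial count by one),
so the package canonicalises the orientation — the two (count, size)
pairs are sorted before evaluation — making swap invariance exact by
construction. No multiple-testing correction is applied across taxa,
mirroring the single-table shading convention of clone-library reports;
the inoculation module likewise reports a Bonferroni column for reference
without applying it.

## Selection rules

"Presence" is raw count ≥ 1 (no floor is defined by the survey).
Relative-abundance thresholds are strict inequalities, per the wording
"less than 97%" and "more than 1%". The four criteria combine as OR;
isolate availability and pathogen exclusion are mandatory AND terms.
Persistence is evaluated per below-ground tissue across the conditions
observed for that tissue, with clone libraries and isolate collections
pooled within a condition; a pooled-across-tissues mode is available.
The 1% abundance criterion considers below-ground samples only (the
criteria sentence scopes the screen to taproots and lateral roots); this
is configurable. The known-PGPB and pathogen genus lists ship as editable
JSON package data — they are data, not code — seeded with the sugar-beet
PGPB genera reported in prior work and a conservative set of plant /
animal / human pathogen genera.

## Inoculation statistics

Each (isolate, repeat) batch carries its own control group; every
seedling's dry weight is divided by the mean control weight of its own
batch and tissue, which removes a multiplicative batch effect exactly
(asserted on a constructed two-batch fixture). The treated ratio sample
is compared against the control ratio sample with Welch's two-tailed t
(Satterthwaite df); the implementation delegates to
`scipy.stats.ttest_ind(equal_var=False)` and is held to the textbook
formulas at 1e-10 in the tests. Whether the original analysis used
per-seedling or per-batch-mean ratios is not stated; per-seedling is the
default and a per-batch-means mode is provided. Effects are classed by
the sign of (mean ratio − 1) at P < 0.05, with the P < 0.01 tier
recorded. The full procedure's type-I error on null synthetic data is
~5% (held to 5% ± 1.5% over 1,000 replicate studies), and power rises
monotonically with the true ratio.

## The synthetic-study generator

The generator emulates the survey design it targets: 12 clone libraries
(4 tissues × 3 fertilisation plots) and 4 isolate collections (2 plots ×
2 media), each 150–180 sequences deep. Counts are multinomial draws with
probabilities ∝ base_abundance × tissue_affinity × condition_stability
(collections additionally × per-medium culturability on the lateral-root
weights). Base abundances are log-normal(0, 1.5), reproducing the
long-tailed rank-abundance shape implied by the survey's high singleton
counts. Background OTUs are split into a culturable generalist class and
an unculturable class (at least one OTU always has culturability 0 on
all media, emulating taxa recalcitrant to cultivation); culturable
OTUs carry an oligotroph/copiotroph bias between R2A and TSA. Planted
roles (two OTUs per role by default) are constructed to satisfy each
selection criterion — novel (identity drawn in 0.90–0.965),
tissue-specific (zero above-ground affinity), persistent, abundant,
known-PGPB genus, plus pathogen-like decoys — and every culturable
background OTU is given one zero-stability condition (so it can never be
persistent) and guaranteed above-ground presence (so it can never be
tissue-specific).

Sequence emission writes one template-derived representative per OTU
(~6% of a 1,200-column template substituted; a post-check enforces all
inter-representative p-distances above threshold + twice the read noise,
with deterministic retries) and per-read variants within 0.8% of their
representative. This geometry makes furthest-neighbour clustering at
0.03 provably recover the planted partition: intra-OTU distances stay
below 1.6%, inter-OTU distances above 3.4%. Substitution-only noise on a
fixed alignment (no indels) keeps the distance stage exact and avoids
realignment. All randomness derives from one seed expanded into
per-stage substreams via `SeedSequence(seed, spawn_key=(stage, ...))`;
identical (design, seed) pairs give byte-identical files.

### Calibration regimes

Expected relative abundances are calibrated by damped iterative scaling
of base weights and below-ground affinities. Two regimes exist:

* **Default (realistic)**: survey depths (150–180), culturable
  background capped at 0.5% expected share below ground with guaranteed
  ≥ 0.8% expected share above ground, planted floors at 2%. At these
  depths the >1% abundance rule is intrinsically noisy for taxa near the
  threshold — a background OTU at 0.5% expected share regularly exceeds
  1% observed in a 165-read sample — so end-to-end candidate screens on
  default studies include such near-threshold background, as they would
  on real data of this depth.
* **Recovery**: `recovery_design()` tightens the background cap to
  0.15% and fixes depths at 1,000 (the regime where sampling depth
  exceeds ~10 / minimum planted abundance). Poisson tail bounds make a
  background threshold-crossing vanishingly rare, and selection then
  recovers the planted candidate set with precision = recall = 1 across
  seeds; the deterministic "expected"-counts sampling mode gives the
  same guarantee at survey depths. These margins were fixed analytically
  at design time.

What passing tests on synthetic data do **not** show: robustness to
chimeras, PCR/sequencing error structure, indels and alignment error,
rRNA copy-number variation, or taxonomy misclassification — none of
which the generator models (deliberately; see its non-goals).

## Problem sizes

The default full-scale synthetic study (~2,600 sequences of 1,200
columns, 120 ground-truth OTUs) mirrors the survey's census and runs the
whole sequence pipeline in well under a minute; the multi-seed
ordination and recovery analyses use 40–60 OTU studies without sequence
emission, which preserve all count-level structure. These sizes are the
package's chosen defaults for its own analyses.

## Known limitations

* The exact statistic of the legacy two-library comparison program is a
  documented stand-in (see above).
* The full-scale OTU census of the original survey (456 OTUs from the
  deposited accessions) depends on its external alignment and distance
  tool and on downloading the deposit; the package asserts the
  structural equivalent (exact planted-inventory recovery at the same
  design scale) instead.
* PCoA axis percentages are alignment- and tree-dependent and are not
  asserted numerically.
* The screen's outcome on shallow (survey-depth) multinomial studies is
  intentionally noisy near the 1% abundance threshold; guarantees hold
  in the recovery regimes described above.
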