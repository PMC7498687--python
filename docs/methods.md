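# Methods

## The model

The pipeline rests on a single biological assumption: a biosynthetic domain
(a KS or AD amplicon) and the 16S rRNA gene of the organism carrying it are
encoded on the same chromosome, so across samples their read counts co-vary
through the producer's cell count. For OBU *i* and species *j* this is the
proportional model

    OBU_i = alpha_ij * species_j + noise,

with no intercept: zero producer means zero domain. The screen fits all
OBU × species pairs by least squares — alphâ = Σxy/Σx², SE(alphâ) =
√(s²/Σx²) with s² = RSS/(n−1), t = alphâ/SE, two-sided p from Student's t
with n−1 degrees of freedom — and keeps pairs with p below a fixed
threshold (default 0.001). No multiple-testing correction is applied, but
the total number of tests is always reported so users can apply their own;
the fixed threshold is the screen's defining property, not an oversight in
this implementation. The degrees-of-freedom convention is switchable to n
(`df_convention="n"`) because software differs on no-intercept models;
statsmodels' OLS without constant matches the n−1 default.

Screening runs on total-sum-normalized abundances (per 100,000 reads) by
default so slopes are comparable across samples of unequal depth; a raw-count
mode exists and is what validation against planted slopes uses, since planted
alphas are defined on raw counts.

## Amplicon processing

Paired domain reads are trimmed from the 3' end to fixed lengths (defaults
240 bp forward, 175 bp reverse; pairs shorter than the targets are discarded
and counted, never padded), joined as `forward + "N" +
reverse_complement(reverse)`, clustered greedily within each sample at 97%
identity, pooled per domain, re-clustered at 95% on the round-1 centroids
(which carry their member counts as abundance weights into round 2), and
clusters whose total pooled membership is a single read are discarded. The
final 95% clusters are the OBUs; the table cell (i, s) is the number of
sample-s reads inside OBU i. Count conservation holds exactly: input pairs =
table total + trim discards + singleton discards.

Greedy clustering is deterministic for any input order: items are sorted by
abundance weight descending, ties broken by sequence then id, and each item
joins the first centroid at or above the threshold. Whether a "singleton"
means one member read (default) or one round-1 centroid is configurable
(`singleton_unit`), as is keeping singletons entirely.

**Identity metric.** Identity is computed from a global Needleman–Wunsch
alignment (match +1, mismatch −1, gap −2) as matching columns divided by
alignment columns, where terminal-gap columns and any column containing N
are excluded from both numerator and denominator — the join spacer must not
penalize, and a length difference costs nothing in the *value*. Terminal
gaps are, however, penalized in the alignment *score*. This matters: with
free end gaps the score-optimal alignment of two unrelated amplicons is a
spurious short overlap (a ~10 bp shared substring scores +10 while the
honest full-length alignment of random sequences scores about −0.5 per
column), and its near-perfect core identity merges distinct OBUs. Penalized
end gaps force full-length alignment of unrelated pairs while the column
exclusion still keeps prefix/suffix relationships at identity 1.

An optional shared-8-mer prefilter skips alignments that provably cannot
reach the threshold (each edit column destroys at most k shared k-mers, with
slack for N columns and offsets); it is required by the tests to leave
results bit-identical to the unfiltered mode. Chimera checking is a
pass-through hook (`chimera_hook`) so an external de novo checker can be
inserted between joining and clustering; no checker is bundled.

## Diversity statistics

All formula-level, on one code path each, cross-checked in the tests against
independent implementations (scikit-bio, scipy, statsmodels, brute-force
enumeration):

- **Chao1** (bias-corrected default): S_obs + f₁(f₁−1)/(2(f₂+1)); classic
  variant S_obs + f₁²/(2f₂) available, falling back to the bias-corrected
  term when f₂ = 0 where it is undefined. Standard errors use the standard
  variance formulas for each case (f₁=0 → 0). Chao1 refuses normalized
  tables: the estimator is undefined off integer counts.
- **Rarefaction**: the closed form E[S_n] = Σᵢ [1 − C(N−Nᵢ,n)/C(N,n)]
  evaluated in log-gamma space; exact binomial-coefficient evaluation and
  Monte-Carlo subsampling serve as oracles in the tests.
- **Normalization**: total-sum scaling to a fixed target (default 100,000;
  columns sum to the target exactly, fractional values flagged
  `normalized`), or seeded hypergeometric rarefaction with shallow columns
  dropped under a warning. Total-sum is the default reading of "normalize to
  a common depth"; rarefaction exists for sensitivity analysis.
- **Bray–Curtis**: 1 − 2Σmin(xᵢ,yᵢ)/(Σx+Σy); zero-total samples are an
  error, and joint rescaling of all samples leaves the matrix unchanged.
- **PCoA**: B = −½HD²H, symmetric eigendecomposition, axes kept above a
  relative eigenvalue tolerance (1e−9 of the leading eigenvalue),
  coordinates = eigenvector·√eigenvalue. Negative eigenvalues are reported
  untouched — no Lingoes/Cailliez correction — because downstream consumers
  should see the metric distortion, not a patched spectrum.
- **Biplot loadings**: loading of feature f on axis k is the Pearson
  correlation of f's abundance with the axis-k coordinates, scaled by
  sd(axis k)/sd(axis 1) so lower-variance axes are down-weighted; constant
  features load 0, and features whose largest |loading| exceeds a cutoff
  (default 0.1) are flagged. This is an unconstrained stand-in for a
  constrained (canonical) ordination's species scores and is not claimed to
  reproduce one.
- **PERMANOVA**: one-way pseudo-F per Anderson with SS_total =
  Σ_{i<j}d²ᵢⱼ/N and SS_within its per-group analogue; p = (1 + #{F_perm ≥
  F_obs})/(1 + n_perm) under free whole-label permutation (no strata), with
  the seed recorded in the result. Note the permutation floor: a permutation
  reproducing the original partition ties F_obs, so the minimum attainable p
  exceeds 1/(1+n_perm) slightly for small designs.
- **ANOVA + Tukey**: scipy's F test and studentized-range Tukey HSD; the
  compact letter display assigns letters to maximal cliques of the
  non-significance graph (groups sharing a letter are not distinguishable at
  alpha = 0.05). Tukey is always computed; the convention of consulting it
  only when the ANOVA is significant is left to the caller (the result
  carries `significant`).

## Cleaning and species de-duplication

Features present in at most one sample **and** with fewer than 10 total
reads are removed before screening; the conjunction is the default reading
of the rule, an OR mode exists, and the removal report names every feature
and which condition(s) fired so the ambiguity stays visible. Species with
pairwise Pearson r² = 1 (within 1e−12) are grouped by transitive closure and
only the highest-total member survives; zero-variance species have undefined
correlations and are removed with reason "constant".

## The synthetic community generator

The generator is the package's instrument for validation, not a fixture: it
emulates the statistical structure the analysis assumes and exposes the
ground truth.

- **Species abundances**: per-species log-normal weights (`abundance_logmean`
  = 0, `abundance_logsd` = 1.5 by default) shared across samples,
  multiplied per sample by independent log-normal replicate jitter
  (`replicate_jitter_sd` = 0.2), optionally masked by per-(species, sample)
  Bernoulli presence (`species_occupancy`, default 1 = dense), renormalized
  and drawn multinomially to `count_depth` — every column sums exactly to
  the depth.
- **Producers**: `n_producers` species each carry `obus_per_producer`
  planted OBUs with slopes drawn uniformly from `alpha_range` (a placeholder
  law — no empirical slope distribution exists for real OBU–species pairs).
  A configurable fraction of producers is forced below a relative-abundance
  ceiling (default 0.001, i.e. 0.1%) by construction.
- **OBU counts**: negative-binomial around alpha·species count with
  Var = mu + dispersion·mu²; dispersion → 0 is implemented as deterministic
  rounding of the mean, so planted proportionality is exactly recoverable in
  the noise-free limit. Background OBUs belong to unobserved taxa: each gets
  its own log-normal across-sample trajectory (and occupancy mask),
  independent of every species in the table. A flat background profile would
  trivially violate the no-intercept null — a flat positive y fits a
  positive slope on any flat positive x — so flatness is a modelling error,
  not a neutral choice.
- **Sequence mode**: each OBU receives a random centroid locus (pairwise
  identity verified below 90%); forward reads copy its 5' end and reverse
  reads the reverse complement of its 3' end (defaults 300/300 bp so the
  240/175 trimming is exercised), mutated at ≤1% per base so within-OBU
  identity stays ≥98%; read counts per (OBU, sample) are uniform on
  `reads_per_obu` and the read→OBU truth map is recorded.
- **Determinism**: three independent RNG streams (community, OBU counts,
  reads) derive from the master seed, so each piece regenerates identically
  in isolation.

What the generator does **not** emulate: quality-score error models, chimeras,
primer degeneracy, taxonomic mis-assignment, and — importantly — any
phylogenetic or ecological correlation among species beyond the compositional
coupling the multinomial induces. Passing tests therefore certify the
pipeline's behaviour under the model's own assumptions, not its performance
on real sequencing artefacts.

## Behaviour of the screen under the null, and the study conditions used

Two properties of the fixed-threshold no-intercept screen shape the
validation design; both are properties of the method, not of this
implementation.

**The null of the t test is E[y|x] = 0, not independence.** For positive
count profiles independent of x, the screen still fires: writing c for the
*uncentered* correlation Σxy/√(Σx²Σy²), the t statistic satisfies t² =
(n−1)c²/(1−c²), and two vectors in the positive orthant have c bounded away
from zero (two flat profiles have c ≈ 1; two heavy-tailed profiles co-peaking
in one sample likewise). Measured over independent log-normal profiles, the
per-pair pass rate at p < 0.001 never falls below about 2% for any
combination of sample count and spread. Calibration of the *statistic* is
therefore checked on its actual null — zero-mean Gaussian deviation profiles
independent of the species — under which t is exactly t_{n−1} conditional on
x. Each test draws a fresh deviation vector: sharing one OBU vector across
many species leaves the mean pass rate at the nominal level but inflates its
variance several-fold beyond binomial, which no implementation could bring
inside a binomial band.

**Specificity comes from sparsity and contrast, not from the threshold.**
The low-abundance-producer experiment (the package's headline validation)
uses conditions chosen from the analysis above: 8 samples (the t threshold
at p < 0.001 rises steeply as df falls, which is what rejects spurious
pairs), 120 species classified one per genus, an even community
(`abundance_logsd` 0.8, so no dominant species drives compositional
common-mode in which all rare features co-vary with the inverse of the
dominant total), per-species occupancy 0.5 (realistic presence/absence
sparsity), cross-sample variation sd 1.0, NB dispersion 0.05, and 10
producers at <0.1% relative abundance carrying 15 OBUs each — producers are
planted as low-abundance/high-OBU genera, matching the regime where the
method's qualitative claim lives. Under these conditions every planted link
is recovered, producer genera occupy the top ranks of the genus-potential
ordering (all within the top fifth of 120 genera; enrichment over
non-producer genera at Mann–Whitney p ~ 1e−6) above a residual spurious
background of a few percent per pair, and the regression of genus abundance
on linked-OBU count yields r² ≈ 0 — abundance is nonpredictive of
biosynthetic potential by construction, and the pipeline detects it.
"Among the top genera" is asserted as rank enrichment rather than an
exclusive top-K list precisely because the spurious background is intrinsic.

Other validation runs and their problem sizes: statistic oracles on 100+
random instances per formula; screen calibration on 25,000 null tests (50
species × 500 fresh deviations, n = 10); PERMANOVA type-I on 200 homogeneous
12-sample datasets at 199 permutations each; planted-slope recovery with 20
links (alpha in [1,5], NB dispersion 0.1, n = 20, accuracy within 15% — note
the per-link relative SE is already ≥ √(0.1/20) ≈ 7%, so the recovered-and-
accurate fraction, not every single slope, is the meaningful statistic);
clustering on ~60–130 read pairs per run from 6 planted OBUs across 3
samples. These sizes keep the full suite under a minute while leaving every
estimate's Monte-Carlo error well inside its assertion band.

## Numerical choices

- Exact fits (zero residual) report t = ∞ and p floored at 1e−300 rather
  than 0, keeping downstream log/compare operations safe.
- The vectorized all-pairs screen uses the same closed forms as the scalar
  `fit_link` and is tested to agree with it pairwise; both are tested against
  a long-double brute-force oracle at 1e−10.
- Cluster and genus orderings break ties deterministically (total count
  descending, then sequence or id lexicographically), so any equal-input run
  is byte-identical, which the demo's determinism check enforces end to end.
- Degenerate inputs fail loudly: empty samples in normalization, zero-total
  samples in Bray–Curtis, groups of size 1 in PERMANOVA, all-constant groups
  in ANOVA, all-zero species vectors in the screen, depths beyond the sample
  total in rarefaction.

## Known limitations

- The screen yields statistical associations, not causal producer
  assignments; horizontally transferred clusters, co-varying consortia and
  compositional coupling all generate links the model cannot distinguish
  from chromosomal co-occurrence.
- The intrinsic few-percent false-positive rate at fixed p < 0.001 on
  positive compositional data (above) means link lists on real data should
  be treated as candidate rankings; the reported test count supports
  explicit multiplicity control.
- The identity metric is exact but O(L²) per pair; the pipeline is built for
  desk-scale validation and amplicon sets in the thousands, not for
  SRA-scale read volumes.
- Chao1 ± values can be read either as estimator SEs (computed here) or as
  spreads across replicates; both are computable from the per-sample results
  and neither is asserted as the only convention.
- The biplot loadings are an unconstrained stand-in for canonical
  (constrained) ordination scores and should not be compared numerically to
  one.
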