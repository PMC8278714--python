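# Methods

This note describes the models and procedures implemented in `boat`, the
choices made where the design was genuinely open, and what the synthetic
panels do and do not establish about real data.

## Data model

Markers are transcriptome-derived SNPs named `gene:position:state` (the
position is 1-based within the gene's CDS). Calls are single IUPAC
characters: A/C/G/T for homozygous calls and R/Y/S/W/K/M for mixed-base
calls. In a panel of doubled-haploid or highly inbred lines a mixed-base
call ("hemi-SNP") usually reflects reads from co-expressed paralogues rather
than residual heterozygosity; the pipeline stays agnostic and treats such a
call as half a dose of each constituent allele everywhere (allele
frequencies, dosage encoding, identity-by-state). `N` is missing; `-` is
accepted on input and normalised to `N`. The marker table's accession column
order is canonical: expression, phenotype and Q matrices are re-indexed to
it, and a mismatch of accession *sets* is an error.

## Marker QC and pruning

Exclusion thresholds: missing fraction > 0.25 or more than 3 distinct call
states remove a marker; optional per-marker `depth`/`qual` columns are
thresholded (10 reads, Q20) when present, since read-level evidence is
produced upstream of this package. Minor-allele frequency is computed on the
dosage scale described above; "minor" is the second most frequent underlying
nucleotide, so MAF is in [0, 0.5] even for 3- or 4-allele markers. Because
the published allele-count rule does not say whether mixed-base codes count
as alleles, both counters are exposed: `n_states` (distinct call characters)
and `n_alleles` (distinct nucleotides after decomposing ambiguity codes).

Two marker sets feed structure inference:

* relaxed — all markers with MAF > 0.05;
* stringent — biallelic, MAF > 0.05, one SNP per gene, markers >= 500 bp
  apart. Within a gene the highest-MAF SNP is kept (tie: lowest position);
  this selection rule is not fixed by the published description, and
  highest-MAF is chosen because it is deterministic and
  information-maximising. When an annotation supplies genomic gene starts,
  retained markers are additionally thinned along each chromosome so
  consecutive markers are >= 500 bp apart on the genomic scale (the
  higher-MAF member of a too-close pair wins). The distance is a parameter;
  500 bp is the default.

## Population structure

`AdmixtureGibbs` implements the Bayesian admixture model with uncorrelated
allele frequencies: ancestry q_i ~ Dirichlet(α,…,α) per accession, allele
frequencies p_kl ~ Dirichlet(λ,…,λ) per cluster and marker (λ = 1), and each
observed allele copy drawn by first picking an origin cluster from q_i and
then an allele from p_kl. A homozygous call contributes two identical
copies, a mixed-base call one copy of each allele, `N` none. The Gibbs sweep
samples copy origins, then P and Q from their Dirichlet conditionals; α is
updated by a Metropolis random walk (step 0.05, uniform prior on (0, 10)),
with a fixed-α mode available. Chains are initialised from the prior
(uniform ancestry, assignments drawn from it) so no cluster starts empty.
The model evidence is estimated as mean(lnL) − var(lnL)/2 over retained
sweeps, and runs are bit-reproducible from an integer seed. Defaults are
10 000 burn-in, 10 000 retained sweeps and 10 replicates seeded seed,
seed+1, …

The uncorrelated-frequencies prior (rather than the correlated F-model) is
the simpler variant and is adequate for strongly diverged crop types; it
also matches the Balding–Nichols generator, which makes parameter-recovery
tests a fair check of the sampler rather than of prior mismatch.

One behaviour worth knowing: on data with *no* structure signal the exact
posterior concentrates on the label-symmetric "everyone in one cluster"
modes, and any label-sticky Gibbs chain (this one, like the classic
implementations) reports one of them rather than the symmetric average
q = 1/K. The tests therefore check what exchangeability actually
guarantees — identical rows across accessions, and no preferred label
across seeds — not a per-accession 1/K.

Model choice across K uses the Evanno table: L′(K) = mean L(K) − mean
L(K−1), |L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)| / sd L(K), with boundary
Ks and sd = 0 reported as undefined rather than infinite. ΔK often peaks at
K = 2 on hierarchically structured panels even when finer substructure
exists, so the final K is a user decision; `best_k` simply reports the
argmax among defined entries.

Replicate Q matrices are aligned by exact search over the K! column
permutations (feasible for K <= 8, the intended range), maximising the sum
of accession-wise dot products with the running consensus; the element-wise
mean of aligned replicates, rows renormalised, is the consensus Q. The
exact search replaces greedy heuristics because at this K it is both cheap
and provably optimal, which simplifies testing.

Validation views: PCA scores of the mean-imputed, column-centred dosage
matrix (deterministic sign convention), and a neighbour-joining tree on
1 − IBS distances (identical calls 1, mixed-base vs constituent homozygote
0.5, disjoint 0; pairs averaged over co-observed markers). Negative NJ
branch lengths are clamped to zero. The 1 − IBS distance is appropriate
because the lines are fixed; allele-sharing refinements are out of scope.

## Association scans

The marker scan is a Gaussian general linear model per marker: ordinary
least squares of the trait on [intercept, structure covariates, minor-allele
dosage], with the dosage term tested by a partial F-test (full vs reduced
model). "Generalised linear model" here means the classical fixed-effects
GLM used for continuous traits, not a link-function GLM — the traits are
days. Dosage is 0/1/2 with mixed-base calls scored 1 (the midpoint,
consistent with the half-dose MAF convention); the minor allele is the rarer
one, ties broken alphabetically. Q-matrix correction uses K−1 ancestry
columns (the rows sum to one, so the full matrix is collinear with the
intercept); PCA correction uses 5 PCs by default. Accessions missing the
trait or the call are dropped casewise per marker and MAF > 0.05 is
re-checked on the used subset; markers collinear with the covariates are
skipped with a logged reason. Marker R² is the incremental sum of squares of
the dosage term divided by the total (centred) trait sum of squares among
used accessions — the natural "variance explained by the marker after
structure" reading of a GLM scan's R² column.

The GEM scan is the expression analogue: per gene with mean RPKM >= 0.5
(re-checked on used accessions), OLS of the trait on RPKM with a t-test on
the slope; structure covariates are optional and off by default, since the
expression model is a plain fixed-effect regression.

Multiple testing uses Storey q-values: π0 is estimated from
π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05, …, 0.95, smoothed with a cubic
spline and read off at λ = 0.95, clamped to (0, 1] (floor 1/m to stay
positive); q_i = min over thresholds t >= p_i of π0·m·t/#{p <= t}. With π0
fixed at 1 this is exactly step-up Benjamini–Hochberg, which the tests
assert element-wise. Hits are rows with q < 0.05, and the Manhattan
threshold line is drawn at the largest p among hits. q-values are computed
per trait scan, not pooled across traits, matching per-trait threshold
lines on the plots.

Linkage disequilibrium is the squared Pearson correlation of dosage vectors
over co-observed accessions, for all marker pairs within an index distance
of 50 in overall marker order (a sliding window over the marker list,
chromosome-agnostic by default with a within-chromosome flag); pairs with
fewer than 3 co-observed accessions are skipped and counted. For unlinked
markers the expected r² is approximately 1/(n−1), which the null panel
reproduces. A per-marker decay view (`ld_decay`) orders r² by index
distance from a focal marker.

The genomic inflation factor (median χ² ratio) is an internal diagnostic
used by the structure-correction tests, not a published quantity. Because a
median over a few hundred markers has sampling sd ≈ 0.2, calibration checks
pool p-values over ~20 generator seeds before estimating it.

## Phenotyping

Traits are DTB (days to buds visible) and DTF (days to first flower)
counted from the end of vernalisation (day 0), so stages reached during
pre-growth or vernalisation are negative. Per-accession values are replicate
means; replicates that never reached a stage are missing, and records with
the flower before the buds stage are rejected with a log entry.
Non-vernalised treatments have no cold-exit day of their own, so a
configured reference day is used (all plants left vernalisation on the same
calendar day by design, which makes one reference day exact). Contrast
traits are plain differences, missing when either side is missing. Group
comparisons use the two-sided Wilcoxon rank-sum test, W reported on the
Mann–Whitney scale (rank sum of the first group minus n_a(n_a+1)/2), exact
by enumeration for n_a+n_b <= 20 without ties and by the
continuity-and-tie-corrected normal approximation otherwise. The sampling
unit is the per-accession treatment mean. Expression–trait R² is the squared
Pearson correlation, with an "extremes" mode restricting to the k lowest-
plus k highest-expressing accessions by the gene's RPKM.

## Synthetic panels

The generator draws K subpopulations under the Balding–Nichols model:
ancestral frequency p ~ Uniform(0.05, 0.95), cluster frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), accession frequency = ancestry-weighted
mixture. Lines are mostly pure (one home cluster plus an admixed fraction of
mean ~0.1–0.15), as in a panel of distinct fixed crop types. A call is one
allele drawn and written homozygous; a small fraction (2 % by default)
becomes the mixed-base code of the marker's two alleles and 3 % become
missing. Markers are spread over genes (at least one each) with within-gene
positions spanning 1–3000 bp so the pruning rules are exercised, and an
annotation with genomic gene starts is produced. Expression is log-normal
with optional per-cluster log shifts and optional exactly-zero accessions
for the causal gene; traits are population effect + β·dosage + γ·RPKM +
Gaussian noise, one independent noise draw per named trait.

Named profiles fix the study conditions: `null` (69 lines, 1000 markers, no
structure, pure-noise trait, sd 10 days), `structured_confounded` (90
lines, 3 clusters, F = 0.3, 200 markers, cluster effects −15/0/+15 days),
`causal_marker` (as before plus one common biallelic causal marker with β
solved so it explains 25 % of trait variance), `causal_gem` (69 lines,
slope 1.5 days per RPKM, unit noise), and `flc_like` (69 lines, 4 clusters,
five zero-expression accessions, the high-expressing cluster shifted +2 on
the log scale, γ sized at 0.8·σ/sd(RPKM) so the panel-wide correlation is
weak while the zero/high extremes correlate strongly). Effect sizes that
depend on realised variances (β, γ) are computed from the generated data at
build time, deterministically per seed.

What the panels do not emulate: linkage between markers (markers are
exchangeable given ancestry, so LD comes only from structure), realistic
allele-frequency spectra, shared expression programmes between genes, G×E
structure across treatments, or censoring of never-flowering lines. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not performance on any particular real panel; the
published headline marker lists depend on the archived sequencing-derived
tables and are outside desk scale.

## Numerical choices

OLS uses `lstsq` with rank checks; the uncorrected scan uses an
algebraically identical closed-form path (F = (n−2)r²/(1−r²)) vectorised
over markers. p-values are floored at 1e-300 before taking −log10. Q rows
are clipped away from exact zero before the α update's log. Dosage/LD
computations propagate NaN for missing and skip zero-variance vectors.
Tie-breaks are fixed throughout (argmax to the lowest cluster index,
alphabetical minor allele, accession order in trees) so every output is
deterministic given the seed.

Problem sizes in the test suite and acceptance script (panels of 60–90
accessions, 200–1000 markers, chains of 2000 + 2000 sweeps with 3
replicates for K = 1…5) were chosen as the smallest designs at which the
expected effects are decisive — e.g. the Evanno peak at the true K and
>95 % assignment accuracy — while a full suite run stays in the minutes
range on a single core.
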