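# Methods

## Data model

Count tables are taxa × samples with non-negative integer bodies at one of
three levels: sequence variant, species, genus. Aggregation sums variants by
label; at species level, variants without a species call pool into a
reserved `others` taxon, while genus-level "unclassified *<family>*" labels
remain distinct taxa. Relative abundances are percentages per sample.
Metadata binds each sample to (subject, site ∈ {SA, TO, SU}, time ∈ {t0, t1,
t2}, arm ∈ {control, juice}); the triple (subject, site, time) must identify
a sample uniquely.

Prevalence is always computed within the sample subset being analysed (per
site), pooling all three time points; the contaminant screen uses the strict
form (fraction of non-zero samples **>** threshold), the differential
screens the inclusive form (**≥** threshold). Both default to 10%.

## Species assignment

Type-strain 16S records are trimmed to the amplified V1–V2 region between
the primer sites (forward `AGRGTTHGATYMTGGCTCAG`, reverse
`TGCTGCCTCCCGTAGGAGT` matched as its reverse complement; one mismatch per
primer is tolerated because type-strain records carry sequencing errors).
A variant is compared to each fragment by a semi-global *fit* alignment:
the shorter sequence is aligned in full, end gaps are free on the longer
sequence only, and the mismatch count is substitution plus internal gap
columns at unit weight, with IUPAC ambiguity codes matching their base
sets. A species name is assigned only when exactly one species has a
fragment within two mismatches; ties produce a "related to …" annotation
instead. A fully end-free alignment was rejected because its optimum for
dissimilar sequences is a spurious short overlap with zero mismatches,
which would make the two-mismatch threshold meaningless. Whether indel
columns count as mismatches is an assumption (they do here); the alignment
is intended for homologous fragments of the same amplicon region.

## Contaminant network

Spearman correlations (average ranks for ties; constant taxa give missing
values, never edges) are computed between species with strict prevalence
> 10% across subgingival samples only, where biomass is lowest and
contamination clearest. The network keeps edges with rho **strictly** above
0.7 — positive correlations only, since a shared contaminant load can only
induce positive co-variation, and the threshold is read as the correlation
coefficient (a p-value of 0.7 would not describe "strong" correlation.)
Clusters are connected components containing a configured seed species.
A species is removed when it lies in a seed cluster and has at least three
edges to other members of that cluster (the seeds themselves are always
removed); a global-degree variant is available as a switch. Removal is
applied to all sites' samples, and the removed read count is reported.

## Alpha diversity

Samples are rarefied once, without replacement (multivariate
hypergeometric), to the smallest library size by default, with the seed
recorded; an averaging mode is available but a single recorded draw is the
default because repeated-measures tests downstream want one consistent
table. Shannon H uses the natural logarithm. Group comparisons use ordinary
one-way ANOVA with all-pairs t tests on the pooled residual variance and
Holm–Šidák step-down adjustment.

## Community structure

Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ) is computed on
percent-standardized profiles (for equal-sum vectors this is half the L1
distance, hence a metric on compositions). PERMANOVA uses the
McArdle–Anderson trace formulation: with the Gower-centred inner-product
matrix G of squared dissimilarities and hat matrices from sum-coded design
matrices (intercept + main effects + interaction), the Type III partial SS
of a term is tr((H_full − H_without_term) G), the residual SS is
tr((I − H_full) G), and pseudo-F is judged against permutations of sample
labels (rows and columns of G together). Sum coding makes the partial SS
Type III in unbalanced designs; in balanced designs the term SS plus
residual reproduce the total within 1e-8. p-values use (1 + #{F* ≥ F}) /
(B + 1) with B = 9999 by default; an exhaustive mode enumerates all
permutations for small n. Three permutation schemes are provided: free
(default), within-subject (restricted exchange of times inside each
subject, the defensible scheme for repeated-measures time effects), and
between-subject (whole-subject exchange for the arm factor). Pairwise
tests are two-level PERMANOVAs on the sample pair subset with t = √pseudo-F.

Centroid dissimilarities are computed directly from G:
‖c_A − c_B‖² = mean G_AA + mean G_BB − 2 mean G_AB, which equals the
centroid distance in a principal-coordinate embedding that keeps negative
eigenvalues as imaginary axes (signed squared distances), so no eigenvalue
truncation bias enters; for singleton groups this reduces exactly to the
pairwise Bray–Curtis value. Dispersion follows PERMDISP: distances to
group centroids in the signed principal-coordinate space, a one-way F on
those distances, and a label-permutation p-value.

Non-metric MDS is 2-D Kruskal stress-1 minimisation (scikit-learn), keeping
the best of 50 random restarts seeded from a master seed.

## Time-course screening

Per site and taxon, complete subjects' abundances over t0/t1/t2 enter the
Friedman test (within-subject average ranks, tie-corrected chi-square with
k − 1 df; subjects missing a time point are dropped, and a taxon constant
within every subject scores 0). Benjamini–Hochberg correction is applied
across the tested taxa of that site and level, matching per-site reporting.
Taxa with q < 0.1 receive Dunn's post-hoc in its within-block (Friedman)
form, zᵢⱼ = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/(6n)), with two-sided normal p-values left
unadjusted — a flagged assumption; the paired design is why the
within-block rather than the Kruskal–Wallis form is used. Tiers: *primary*
if q < 0.05; *secondary* if p < 0.05, 0.05 ≤ q < 0.1, and at least one Dunn
pair is significant at 0.05.

## Juice-effect classification

Only t0 and t1 enter (the intervention spans that window). Square-root
transformation stabilises the skewed percent abundances. The two-way mixed
ANOVA (time within-subject, arm between-subject) comes from pingouin; with
two time levels its interaction F equals the squared two-sample t on
per-subject difference scores, which the tests verify numerically. Four
pairwise comparisons — t0 vs t1 within each arm (paired t) and control vs
juice at each time (two-sample t) — are Šidák-adjusted with family size
m = 4 (the family is configurable; the choice is reported in the output).
Verdict order: `excluded_baseline` if the adjusted between-arm t0 p < 0.05;
`effect` if the interaction p < 0.05; `probable_direct` if the juice arm
changed (p < 0.05) while the control arm shows no difference (p > 0.1);
`probable_prevented` for the mirrored control-only change; a between-arm
difference at t1 but not t0 is `probable`, attributed to whichever arm
moved more; anything else is `none`. The ambiguous band 0.05 ≤ p ≤ 0.1 in
the "other" group deliberately yields `none` — only p > 0.1 counts as "no
difference".

## Synthetic study generator

The generator emulates the study design: 22 subjects (11 per arm), three
sites, three times, 198 samples. Counts are Dirichlet-multinomial
(concentration 300) around per-sample expected compositions built from:

* **Site base compositions** constructed block-wise (a core block shared by
  all sites, SA∩TO and SA∩SU blocks, and site-specific blocks, geometric
  rank-abundance within blocks). Because Bray–Curtis between compositions
  is half the L1 distance, block masses directly set the base separations —
  0.05 (SA–TO), 0.32 (SA–SU), 0.37 (TO–SU). These are deliberately smaller
  than the target centroid dissimilarities (22/42/53%) because finite-depth
  sampling noise inflates estimated centroid distances; the masses are
  calibrated so the *measured* centroid dissimilarities land on the targets
  at default settings.
* **Subject effects**: persistent per-(subject, site, taxon) log-normal
  multipliers (σ = 0.6), the within-subject consistency that repeated-
  measures tests exploit.
* **Time effects**: 10 taxa per site, fold 3 applied at t1 and persisting
  at t2 (the magnitude and persistence seen in real screening hits), half
  up, half down.
* **Interactions**: 6 taxa per site, fold 3 at t1 in the juice arm only.
* **Contaminants**: three clusters of six species (each anchored by a known
  kit/paper-point contaminant species), with counts Poisson around a
  per-sample, per-cluster log-normal shared load (σ = 1), added on top of
  the biological counts. The expected contaminant share is 8% — higher
  than a sequencing-scale study would show, because desk-scale depths
  (log-normal, mean ~5,000 reads, minimum 1,000) need countable contaminant
  reads for rank correlations to be informative. A `paper_scale` preset
  raises depths to a mean of 55,000.

Ground truth (contaminant species, signal taxa with direction, site
targets) is exported and re-read losslessly. Identical seeds give
bit-identical outputs.

What the generator does **not** emulate: phylogenetic correlation between
taxa, taxon-taxon ecological interactions, compositional negative
correlation beyond renormalisation, subject covariates (age, sex), and
read-level error. Passing recovery tests therefore show the procedures
detect the planted mechanisms at realistic effect sizes, not that they are
robust to every structure real data can carry.

## Calibration and recovery experiments

The null-calibration sweep uses the generator with *all* effects off —
including subject random effects, since with them on, free permutation of
repeated measures is not exchangeable — at a reduced size (10 subjects,
one site, 1000 replicates, 199 permutations per PERMANOVA). Under this
null, PERMANOVA's time term, the raw Friedman test and the juice
interaction each reject close to the nominal 5%; the BH primary tier stays
at or below nominal (FDR control under a global null keeps the per-taxon
rejection fraction under, not at, 5%). Recovery at full default settings
is measured against ground truth pooled over the three sites: contaminant
flagging sensitivity/specificity, primary-tier sensitivity for planted
time effects, and {effect ∪ probable} sensitivity plus the false-flag rate
among unaffected taxa for planted interactions.

## Numerical choices and limitations

* Permutation p-values use the add-one convention; exhaustive enumeration
  divides by the permutation count.
* Pseudo-F ties in permutations count as exceedances (F* ≥ F − 1e-12).
* Hat matrices use the pseudo-inverse; term df are rank differences.
* Zero-depth samples are rejected before standardization; constant taxa
  are excluded from the correlation network rather than given rho = 0.
* Degenerate juice-effect inputs (one subject per arm, no variance) raise
  rather than return silent results; incomplete subjects are dropped
  per-taxon (complete-case analysis).
* PERMANOVA here covers at most two crossed factors plus interaction;
  nested or three-factor designs are out of scope, as are compositional
  (log-ratio) differential methods and coverage-based richness estimators.
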