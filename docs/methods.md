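# Methods

This note records the models implemented in `splicestrat`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Units and conventions

Every inclusion fraction (PSI) and insoluble fraction lives in [0, 1]
internally; percent scales exist only at file boundaries (readers accept a
declared scale, writers multiply marked columns by 100).  Junction
coordinates are 0-based half-open, matching the Leafcutter counts
convention; strand is not modeled because no analysis step uses it.
Missing measurements are explicit NaN, never zero.

## Composite splicing score and classification

CSS(p) is the arithmetic mean of patient *p*'s replicate-averaged PSIs over
the 14-exon hnRNP H-enhanced panel.  Replicates are averaged per cell
first, then cells are averaged across exons, so a patient with unequal
replicate counts per exon is not silently reweighted.  A patient needs at
least `min_exons = 10` of 14 non-missing panel values to be scored; below
that the patient is flagged and left unscored rather than scored on thin
data (the threshold is this package's choice; the assay design has no
systematic missingness).

Classification: controls are the neurologically normal and SOD1-ALS cases
(SOD1-ALS is not believed to act through RBP aggregation, which is what
makes it usable as a control here).  The cutoff is control mean − k·SD with
k = 3 and the **sample** SD (n−1); the rule is one-sided because only a
*low* CSS is disease-interpretable — a case above the control mean is still
like-control.  No control is trimmed regardless of distance from the mean
(an optional `control_ids` override exists for sensitivity analyses).  The
control-set definition is exposed rather than hard-coded because published
descriptions of such control pools are often ambiguous at the margin.

Leave-one-out regressions refit CSS for each 13-exon subset and regress the
held-out exon's PSI on it (OLS); r² is the squared Pearson correlation.  A
zero-variance predictor yields a flat fit with r² = NaN, deliberately
distinguishable from a true r² = 0.

## Insolubility

Percent insoluble is SI/(SOL+SS+SI) per replicate, then replicate-averaged.
The alternative SI/(SOL+SI) was rejected: all three fractions are blotted
and quantified together, so the denominator should be the full recovered
signal.  No loading-control normalization is applied — the assay quantifies
fraction shares within a lane set, which cancels loading.  Patients without
motor-cortex tissue are excluded from insolubility matrices (the tissue the
fractionation needs).

RNA-seq group assignment precedence: C9 genotype → `C9`; control
(neuro-normal or SOD1) → `control`; clinical FTD symptoms → `FTD`; then
sporadic pure-ALS patients split at 50% hnRNP H insolubility into `ALSlow`
(< 0.50) and `ALShigh` (≥ 0.50); patients left without an insolubility
value are `unassigned`.  Exactly 0.50 goes high — an arbitrary but fixed
tie-break the data never exercises.  The clinical-over-threshold precedence
means an FTD-MND case with low insolubility stays in `FTD` rather than
contaminating the ALS groups.

## Differential splicing

Clustering honors input cluster ids when present; otherwise introns are
grouped per chromosome by connected components over shared start or end
coordinates.  Filters: cluster support ≥ 50 reads summed over introns and
samples, every intron ≤ 500 kb, singleton clusters dropped (one intron has
no alternative usage to test).  Per-sample PSI needs ≥ 10 cluster reads in
that sample (`min_sample_reads`, this package's default — comparable tools
bury the equivalent knob in their defaults).

**The test is a declared stand-in.**  The reference method for this kind of
data fits a Dirichlet-multinomial GLM per cluster.  Here, counts are pooled
across a group's usable samples and a multinomial likelihood-ratio test
compares group-specific usage against shared usage: statistic
2·(ll_sep − ll_shared) ~ χ²(K−1).  Pooling ignores between-sample
overdispersion, which makes the test liberal when biological replicate
variability exceeds multinomial noise; the synthetic generator draws
per-sample counts from exact multinomials, so on simulated data the null is
calibrated (verified empirically: p<0.05 fraction and KS uniformity at 2000
null clusters).  On real tissue data this stand-in would over-call, and its
event counts are not comparable to the published ones — which also depend
on the original consortium sequencing depth and are not reproduction
targets here.  BH adjustment is applied across clusters within a
comparison, and the cluster q propagates to its introns; an intron is a
significant event iff q ≤ 0.1 **and** |ΔPSI| ≥ 0.1 (ΔPSI = mean PSI
difference, group minus control).  Setting the ΔPSI cutoff to 0 reproduces
the "unfiltered" analysis and is provably a superset of the filtered calls.

Sex as a covariate: the optional `stratified_cluster_test` tests within sex
strata and combines p-values by Fisher's method.  The default analysis does
not stratify and the generator has no sex effect, so the stratified path is
exercised by tests but not by the pipeline.

Z-scores are per-event over non-missing samples with the n−1 SD (so a
3-value row maps to −1, 0, 1); constant or under-measured rows are dropped
with a warning.  Hierarchical clustering uses average linkage — correlation
distance for events, Euclidean for samples — on identifier-sorted input for
deterministic linkages; the "fixed" ordering mode instead arranges samples
by subtype then increasing insolubility.  Event ranking uses |Spearman ρ|
against hnRNP H insolubility over pairwise-complete samples (≥ 5), ties
broken lexicographically by event key.

## Clinical association

The 2×2 table rows are like-C9/like-control, columns FTD symptoms/none
(ALS-FTD and FTD-MND both count as FTD symptoms).  Odds ratio is the
cross-product; +inf is reported for a zero denominator with positive
numerator, and a Haldane–Anscombe 0.5 correction is available off by
default.  Fisher's exact test uses the minimum-likelihood two-sided
convention (sum of all tables with point probability ≤ observed), verified
exhaustively against full hypergeometric enumeration for every margin with
N ≤ 30.  Both two-sided and one-sided p are reported: on the published
cohort counts the two conventions straddle the printed p-value, and the
package does not chase any particular software default.

## Synthetic cohort generator

One latent burden b per patient drives everything — the minimal structure
consistent with correlated, graded dysregulation across modalities.  No
mechanism is simulated.

Defaults (SimConfig) and their rationale:

- **Cohort**: 6 neuro-normal, 2 SOD1, 4 C9, 50 sporadic — the studied
  series.  Controls/SOD1 draw b ~ |N(0, 0.03)| (tight, near-zero);
  sporadics are a 50/50 mixture of that control-like component and
  Uniform[0.3, 1]; C9 draws from the high component.  The 0.3 floor keeps
  the high component > 3 control SDs below the control CSS mean by
  construction, which is what the study's bimodal CSS distribution shows.
- **Splicing**: per-exon base PSI drawn once per cohort from U[0.4, 0.9]
  (enhanced) / U[0.1, 0.5] (repressed), avoiding 18 hand-picked constants;
  enhanced PSI = base − 0.35·b, repressed = base + 0.25·b, deterministic
  part clamped to [0.01, 0.99], then replicate noise N(0, 0.04) and a final
  clamp to [0, 1].  Two replicates per measurement, i.i.d. noise,
  mirroring duplicate RNA extractions.
- **Insolubility**: per-protein (base, slope) pairs chosen so the class
  means land near the reported ranges — hnRNP H (0.35, 0.50), TDP-43
  (0.22, 0.65), FUS (0.02, 0.55), hnRNP A1 (0.25, 0.55), GAPDH (0.01, 0)
  as the non-aggregating control; noise SD 0.06; the low-speed (21,000 × g)
  fraction is the high-speed value shifted down 0.15 (gentler pelleting
  captures less).  SOL/SS/SI intensities realize the drawn fraction exactly
  against a random lane total, so densitometry round-trips are checkable to
  1e−9.  Motor cortex is missing at rate 0.2 (39 of ~50 cases had tissue in
  the source cohort).
- **FTD risk**: P(FTD | b) = logistic(−2.2 + 3·b): ~10% at zero burden
  (sporadic ALS baseline) rising to ~70% at b = 1, yielding ~a third of the
  cohort FTD-symptomatic, as observed.
- **Junctions**: 300 clusters of 2–3 introns sharing a donor, usage from
  Dirichlet(5); 10% are burden-responsive, shifting the first intron's
  usage by ±0.3·b with proportional redistribution; per-sample totals
  Poisson(100), counts multinomial.

What the generator does **not** emulate: overdispersed junction counts,
sex-linked or batch effects, RNA-quality artifacts (the source cohort's one
degraded control), exon-specific effect sizes, annotation structure beyond
one synthetic chromosome, and any mechanistic coupling between modalities
beyond the shared scalar.  A green parameter-recovery test therefore
establishes that the pipeline's statistics recover the latent structure
they target at realistic effect and noise levels — not that the stand-in
test is robust to real-data overdispersion, and not any biological claim.
The panel's gene symbols include the named target genes plus placeholder
symbols (suffix `x`) filling the panel to its documented 14 + 4 size.

## Determinism and tolerances

All randomness flows through one `numpy` Generator seeded from SimConfig;
identical configs give byte-identical written cohorts.  Written fractions
carry 9 decimals (round-trips asserted at 1e−6); linkage tie-breaks and
table row orders are fixed by identifier sorts.  Test runtimes are kept
inside CI budgets by disabling the junction simulation (`n_clusters=0`) in
the 200-seed loops whose statistics do not use junctions, and by running
integration tests on a reduced cohort; the full default configuration is
exercised once per session by the acceptance suite and the acceptance
script.
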