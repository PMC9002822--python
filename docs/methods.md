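# Methods

This note documents the models behind `ssrmine`, the defaults and why
they were chosen, what the synthetic-data generators emulate, and the
numerical choices a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

Both panels are inbred, so a genotype call is a single allele per
accession and locus: an integer PCR fragment size in bp, `NULL` (the
locus amplified no product), or missing. `NULL` is a first-class allele
state, not missing data: the non-amplified class is heritable, it enters
kinship and (optionally) diversity computations as an allele, and it is
the baseline carrier group for allele phenotypic-effect values. The
rare-allele filter (default: mask alleles at frequency ≤ 5% as missing)
therefore never removes `NULL` calls.

Phenotypes are long-format replicated measurements in cm for the six
height-architecture traits (PH, PL, 1IN–4IN). All analyses operate on
accession replicate means; `env="combined"` means the mean of
per-environment accession means, so unbalanced replication in one year
does not bias the combined value.

## Synthetic natural population

The generator emulates a diverse inbred rice panel: 504 accessions, 262
multi-allelic SSR loci (2–25 alleles, labels 100 + 2k bp so the I/O paths
are exercised realistically), 8 subpopulations.

* **Admixture.** Accession proportions are symmetric Dirichlet(α) with
  α = 0.005, which makes ~92% of accessions assignable at Q > 0.9 —
  matching a panel in which 474 of 504 accessions pass that threshold.
* **Differentiation.** Subpopulation allele frequencies follow a
  Balding–Nichols-style Dirichlet around a shared ancestral vector with
  divergence F = 0.5. Under these defaults the realized panel shows
  mean gene diversity ≈ 0.74, mean PIC ≈ 0.71, ~87% highly informative
  loci (PIC > 0.5), AMOVA ≈ 49% of variation among subpopulations and
  mean pairwise Fst ≈ 0.50 — the regime of a strongly structured,
  geographically sampled rice germplasm collection
  (`scripts/acceptance.py` recomputes these numbers).
* **Null alleles.** 30% of loci segregate a null allele, capped at an
  ancestral frequency of 0.25 so the baseline class stays a minority;
  loci that drift to an all-null panel are redrawn. Per-call missing
  rate is 1%.
* **Loci are exchangeable** — there is no linkage and no built-in LD.
  LD statistics on simulated data therefore measure the null (plus
  structure-induced associations); the D′ machinery itself is validated
  on constructed haplotype tables.

Phenotypes: value = intercept + planted allele effects +
admixture-weighted subpopulation offsets (SD 5 cm by default; heritable
height traits in a structured panel genuinely differ between
subpopulations, and this stratification is exactly what the Q+K model
must correct) + accession-level polygenic noise (SD 5 cm) + environment
offset + replicate error (SD 2 cm). The truth record carries realized
σ²g, σ²e and the implied broad-sense h² = σ²g/(σ²g + σ²e/n), which lands
in the 0.9+ range typical of these traits under the default SDs.

**What passing tests do and do not show.** The generator has closed-form
truth and exchangeable loci; passing recovery tests demonstrates the
estimators are correct under the stated model, not that real SSR panels
satisfy it (real panels have linkage, genotyping error, allele-size
homoplasy and non-Dirichlet structure).

### Planting detectable QTL

A structure-corrected scan can only detect effects that vary within
subpopulations: an allele that doubles as a subpopulation indicator is
absorbed by Q and K — as it should be, since such effects are
statistically indistinguishable from stratification.
`choose_qtl_marker` therefore selects, for simulation studies, the
allele with the smallest frequency spread across truth-assigned
subpopulations (default frequency 0.15–0.7, ≥ 10 null carriers at the
marker so the PEV baseline exists).

## Synthetic CSSL panel

53 lines by default; each line carries 1–3 donor segments of 10–40 cM
placed uniformly on the genetic map (markers spread over 12 chromosomes
of 100–180 cM), everything else background. A marker is donor-typed iff
it falls inside a segment. Phenotype: baseline + Σ(±1 coding × additive
effect) + line-level noise shared by replicates. With ~2 segments per
line the expected donor count at any one marker is small, so recovery
studies plant the QTL at the best-covered marker — mirroring real CSSL
panels, which are designed for coverage rather than sampled at random.

## Diversity and structure statistics

* Gene diversity He = 1 − Σp²; PIC = He − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein);
  classes: high (PIC > 0.5), moderate (0.25 < PIC ≤ 0.5), slight.
  NULL is excluded from frequencies by default (`include_null` switches).
* Nei's standard distance D = −ln(J_xy/√(J_x·J_y)) with the J terms
  averaged over loci before the log. Pairs with J_xy = 0 return a
  flagged sentinel of 30.0 instead of infinity so neighbor-joining stays
  finite.
* Neighbor-joining delegates to scikit-bio's Saitou–Nei implementation;
  negative branch lengths are reported as-is with an optional clamp.
* Evanno ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd L(K) for
  interior K; a K with zero replicate scatter is flagged undefined
  rather than dividing by zero.
* AMOVA uses squared distances = allele mismatch counts across co-scored
  loci, the standard one-level decomposition, and a label-permutation p
  with the add-one correction (b+1)/(m+1). Negative among-group
  components are reported raw and truncated at 0 only for percentages.
* Pairwise Fst is a Weir–Cockerham-type θ with haploid-equivalent
  counts, accumulated ratio-of-sums over alleles and loci. The haploid
  form is appropriate because inbred lines contribute one allele each.
* Multi-allelic D′ = ΣᵢΣⱼ pᵢqⱼ|Dᵢⱼ/Dmax,ᵢⱼ|; inbred calls are observed
  haplotypes, so no phasing. Permutation p-values shuffle one locus's
  calls; the default 1,000 permutations (10,000 via CLI) is a desk-scale
  default — production analyses historically used 100,000.

## Q+K mixed-model association

Kinship is allele-sharing similarity (NULL counts as a class), centered
by the mean off-diagonal value, truncated below at 0, diagonal 1. The
truncation routinely breaks positive-semidefiniteness slightly; a
minimal ridge is added (logged) before factorization.

REML under the no-marker null profiles a single variance ratio
δ = σ²g/σ²e on the kinship eigendecomposition (bounded scalar search on
log δ in [−12, 12], tolerance 1e-8). The fitted components are reused
for every marker (the population-parameters-previously-determined
strategy); a per-marker GLS with the frozen components is still exact
for markers with missing calls because the whitening is recomputed on
the scored subset.

Markers enter as a categorical allele-class term with the most frequent
allele as reference and NULL as an ordinary class; the test is an
omnibus F on the whitened data, so one p-value per marker — matching how
SSR association results are reported (one row per marker, not per
allele). Markers with fewer than two classes are skipped and logged.
PVE is defined (the field does not standardize it for mixed models) as
the marker's reduction in residual sum of squares divided by the total
sum of squares of the whitened response, ×100. Accessions with maximum
admixture ≤ 0.9 are excluded before scanning by default, replicating the
usual pre-mapping filter; `q_threshold=None` retains them.

In the identity-kinship, no-Q limit the whitening is a scalar and the
test reduces exactly to one-way ANOVA — the suite asserts agreement to
1e-9. On stratified null panels the empirical type-I rate at α = 0.05
stays inside the binomial band, and genomic-control inflation is smaller
than the naive uncorrected model's.

BH-FDR delegates to statsmodels' step-up implementation; the test suite
checks it against a literal evaluation of the step-up definition.
"Stable" markers are those FDR-significant in every environment.

## Allele effects and breeding operations

PEV aᵢ is the raw mean contrast against null carriers. By design it is
*not* structure-corrected: in a stratified panel PEVs absorb
subpopulation differences, which is why recovery studies evaluate them
on unstructured phenotypes and why the association scan, not the PEV,
decides significance. When a marker lacks null carriers the default is
an explicit error; a population-mean fallback baseline exists but is
opt-in, to stay faithful to the null-baseline definition.

Mean separation: one-way ANOVA across allele-carrier groups, then either
Duncan's multiple-range test (studentized-range quantiles at protection
level 1−(1−α)^(span−1), harmonic-mean group size, ranges tested
widest-first with non-significant ranges shielding their sub-ranges) or
protected LSD (pairwise pooled-variance t-tests gated on a significant
omnibus F), α = 0.05, compact letter display by insert-and-absorb.
Singleton classes are dropped (logged).

The typical carrier of an allele is the carrier whose replicate-mean
phenotype is closest to the carrier-group mean, ties broken by the
lexicographically smallest accession ID — a documented stand-in for an
otherwise informal notion.

Heritability: σ²e = MS_error, σ²g = (MS_accession − MS_error)/n truncated
at 0, h² = σ²g/(σ²g + σ²e/n); unbalanced replication uses the
harmonic-mean replicate number (logged).

Cross prediction scores each parent pair by the distinct favorable
alleles the two parents jointly contribute over the associated loci; the
predicted increment aggregates each covered locus's best contributed PEV
— mean by default, sum as an alternative. The mean is the default
because summing per-locus best PEVs wildly overstates plausible gains
when loci are correlated and PEVs share the same baseline noise; the
aggregation is an explicit config, not a claim about the right answer.
Ranking is by (allele count, |increment|) and is symmetric in parent
order.

## RSTEP-LRT for CSSLs

Markers are coded +1/−1 (a 0/1 switch exists), so the reported additive
effect is half the substitution effect and the published arithmetic
"substitution changes the trait by twice the additive effect" holds.
Exactly collinear marker columns (segments spanning several markers) are
collapsed to one representative before selection and re-expanded in
reporting with the block members attached.

Stepwise forward-backward OLS selects cofactors with entry p ≤ 0.01 and
exit p ≥ 0.02. These are deliberately stricter than the 0.05/0.10 habits
of textbook stepwise regression: the selection screens every marker, and
in null simulations (53 lines × 60 markers) raw-0.05 entry admits up to
~9 noise cofactors and lets ~14% of pure-noise scans clear LOD 2.5,
whereas 0.01/0.02 keeps false-positive scans at ~2% with no loss of
power at a planted 5 cm effect. Both thresholds are config keys. When
testing marker m, cofactors with |genotype correlation| > 0.7 to m are
dropped from the background model so an overlapping segment cannot
absorb the tested marker's own effect (`cofactor_r_max`).

LOD = n·ln(RSS_reduced/RSS_full)/(2·ln 10) from two OLS fits; PVE =
marker sum of squares / total sum of squares ×100; threshold LOD 2.5.
QTL names follow the standard rice grammar qTRAIT-CHR(.k). Substitution
gains are exposed as two explicit modes — `sum_add` (Σ Add) and
`twice_add_per_locus` (Σ 2·Add) — because published arithmetic uses both
conventions depending on whether a single substitution or a summed
additive prediction is quoted; the package does not guess between them.

## Problem sizes in the checks

The acceptance script and test suite use scaled study designs chosen as
sensible desk-scale experiments: full default conditions (504 × 262,
K = 8) for the diversity/structure summaries; 10–12 panels of 150–300
accessions × 40–45 loci for mixed-model calibration and power; 50 seeds
for heritability (300 accessions × 3 reps) and ΔK recovery; 100 seeds of
53-line CSSL panels for scan recovery. The acceptance run completes in
about a minute on one CPU.

## Known limitations

* No linkage or LD in the natural-population generator; no selection or
  drift dynamics; no coalescent genealogy.
* One allele per accession: heterozygous or polyploid data are out of
  scope.
* The mixed model is single-trait, single-environment; no multi-trait or
  G×E joint modeling, no epistasis.
* CSSL mapping is marker-based (no interval mapping between markers) and
  assumes replicate means per line; replicate-level mixed modeling is
  not attempted.
* PEVs are raw contrasts; in structured panels they conflate allele
  effects with subpopulation means (documented above, by construction).
* STRUCTURE's admixture MCMC is consumed, not reimplemented: the
  pipeline takes Q matrices and replicate log-likelihoods as inputs
  (truth Q from the simulator).
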