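# Methods

This note documents the models, algorithms and design choices behind
`orchardgs`, a toolkit for genomic selection in pedigreed, multi-family,
clonally evaluated crops (the motivating case is apple breeding: large
full-sib families, ordinal 1–5 culling-trait scores, a high-density training
SNP array and a cheap low-density assay for selection candidates).

## Synthetic study populations (`simdata`)

The generator reproduces the statistical structure the analysis assumes
rather than any particular dataset.

**Pedigree.** Unrelated founders are crossed into a pool of parents
(default 24 parents from 12 founders, so parents share ancestors), training
full-sib families are crosses of pool members (default 20 families of 49,
≈980 individuals), and application families reuse training parents at
exactly `round(shared_parent_fraction × n_application_parents)` slots
(default 0.5; default family sizes 662/172/269/109/178). These defaults
mirror a commercial multi-family design in which most selection candidates
have at least one parent inside the training population.

**Genotypes.** Founder haplotypes are drawn independently per SNP from
per-SNP allele frequencies (uniform on (0.1, 0.9) by default) — i.e. in
linkage equilibrium, so all LD in the data is created by the pedigree, which
is exactly the long-range family LD the multi-family design relies on.
Descendants receive one recombinant gamete per parent with the Haldane
mapping r(d) = (1 − e^(−2d/100))/2 for adjacent-marker distance d in cM and
no crossover interference (standard simulation choice). The default genome
is 17 chromosomes × 460 evenly spaced markers on 79.4 cM each (≈7.8K SNPs,
≈1350 cM, ≈6 markers/cM); the desk-scale preset used by the analysis
drivers and most tests is 5 × 200 markers on 100 cM.

**Trait architecture.** A fraction `pi_true` of SNPs (uniform draw) gets a
zero-mean normal effect, rescaled so the realized variance of true breeding
values (TBVs, centered-dosage × effect sums) equals the additive variance
implied by the target h² on a unit-variance liability. Non-causal effects
are exactly zero.

**Phenotypes.** liability = TBV + year effect + location effect + normal
residual, with the residual variance set so var(TBV)/(var(TBV)+var(e))
equals the target h²; the ordinal score is 1 + the number of thresholds
below the liability. Default thresholds cut N(0,1) into five equal classes;
a skewed preset (`SKEWED_THRESHOLDS`) puts ≈85% of mass in score 1 to
emulate defect traits such as fruit cracking. Training families are scored
at one location in ≥2 years, application families in a single year;
29 reference genotypes — clones with no pedigree links, each with its own
latent genetic value — are scored in every year × location cell and are the
only connection between environments.

**What the generator does not emulate:** genotyping error on the arrays,
null alleles and paralog interference, dominance/epistasis, genotype ×
environment interaction, biennial bearing, multi-allelic QTL, and
population-level (ancestral) LD. Tests passing on these simulations
demonstrate internal correctness of the estimators under the stated model,
not performance on real array data.

## Pedigree relationships (`pedkin`)

The numerator relationship matrix A is built with the tabular method on the
topologically sorted pedigree: a_ii = 1 + F_i with F_i = a_sire,dam/2, and
a_ij = (a_j,sire(i) + a_j,dam(i))/2. Unknown parents contribute nothing
(treated as unrelated, non-inbred founders); orphan parents referenced but
never listed are added as founders. O(n²) memory is accepted — the target
scale is a few thousand individuals. Validation rejects cycles (an
individual that is its own ancestor) naming one individual on the cycle.
Correctness is checked against a gene-dropping estimate of 2×kinship
(unique founder allele labels dropped through the pedigree, 20 000
replicates).

## Phenotype adjustment and BLUP (`phenoadj`)

A two-stage scheme: (1) year and location effects are estimated by ordinary
least squares on the reference-genotype records only, with genotype
identity as a blocking factor and the first (sorted) level of each factor
constrained to zero; (2) scores are adjusted by subtraction, per-individual
means are taken, and the animal model y = μ + a + e with a ~ N(0, A σa²) is
fitted. A joint model was the alternative; the two-stage form was chosen
because only the replicated reference clones connect locations, and because
it keeps the adjustment reusable for application families scored in a
single year. Ordinal scores are treated as continuous throughout.

**REML.** EM-REML with the eigendecomposition A = UDU′ of the phenotyped
submatrix: after rotating y, V is diagonal, each EM update is O(n), and the
only O(n³) cost is the factorization. Tolerance 1e−6 on the relative change
of both components; max 10 000 iterations (EM steps are cheap here and its
convergence tail is slow — estimates were verified against a profiled
restricted-likelihood optimum). When both components collapse below 1e−12,
h² is reported as 0 by convention. Estimated h² on BLUP-scale data exceeds
the per-record liability h² by design: adjusted means average over ≥2
seasons (shrinking the residual), and location is partially confounded with
family, so fixed-effect mis-estimation inflates the between-family additive
variance. This mirrors the gap between plot-level and entry-mean
heritability familiar from breeding trials.

**BLUP.** Henderson's mixed-model equations with λ = σe²/σa², solved dense;
individuals in A without records are predicted through their relationships.
σa² = 0 returns all-zero BLUPs with a warning. Checked against the direct
GLS identity â = σa² A V⁻¹(y − Xβ̂).

## Family imputation (`famimpute`)

A transparent two-step stand-in for pedigree/linkage imputation software:

1. **Parent phasing.** For each high-density parent, the allele it
   transmitted to each offspring is deduced wherever the mate's genotype
   leaves a single feasible value. Heterozygous markers are then chained
   per chromosome by a minimum-recombination vote; the vote for a marker
   pools up to the 8 previous informative het markers (nearby markers
   rarely recombine, so pooled votes remain reliable; strictly adjacent
   votes fail at markers where the mate is also heterozygous and no
   offspring is informative). An uninformative stretch starts a new phase
   block with arbitrary orientation — downstream, a block flip just looks
   like one extra crossover. Parents with >5% Mendelian conflicts against
   their offspring raise an error.

2. **Origin decoding.** Per offspring and chromosome, a 4-state HMM over
   (paternal haplotype × maternal haplotype) origins: transitions between
   adjacent markers are independent per parent with Haldane r(d); emissions
   compare the observed dosage with the dosage implied by the parental
   haplotype alleles, with error rate ε = 0.01 (mismatches get ε/2 each;
   unphased het parent markers contribute 0.5/0.5 allele probabilities).
   Forward–backward posteriors fill untyped markers with expected dosages
   in [0, 2]; hard calls are rounded expectations; observed genotypes pass
   through unchanged. Offspring with >5% Mendelian-impossible observations
   are flagged and imputed with a 10× inflated ε.

Sporadically missing entries in otherwise high-density data are refilled
through the same machinery (phase the parents from the nearly complete
family, take the posterior hard call); individuals without two genotyped
parents fall back to the population modal dosage restricted to the parents'
feasible transmission range, then to the rounded expected dosage. The
simple marginal rule alone cannot exceed ≈70% concordance at markers where
parents are heterozygous, which is why the linkage-aware route is the
default.

On the masking experiment (5 chromosomes × 300 markers, ~3.7 cM panel, both
parents at high density, 10 array-typed sibs for phasing) hard-call
concordance is ≈0.96; it degrades monotonically as the panel is thinned to
20 cM gaps.

## BayesC-pi (`bayescpi`)

Whole-genome regression y = 1μ + Wβ + e with the point-mass mixture prior
β_m = 0 with probability 1 − π, β_m ~ N(0, σβ²) otherwise; common σβ²; π ~
Beta(1, 1); σβ², σe² scaled-inverse-χ² with ν = 4.2 and scales set from
var(y) split by an assumed h²₀ = 0.5 (the σβ² scale is spread over the
expected number of included SNPs at π₀ = 0.5). Per sweep the sampler
updates each (δ_m, β_m) pair from its full conditional using the running
residual, then μ (flat prior), σβ², σe², and π ~ Beta(1 + Σδ, 1 + p − Σδ).
The inner loop is compiled with numba. Reported SNP effects are posterior
means of δβ (Rao-Blackwellized through the excluded-state zeros), matching
the convention in which most "SNP effects" of a sparse trait are very close
to zero. Chain defaults are 50 000 iterations / 10 000 burn-in / thinning
10; the tests and drivers use 12 000 / 3 000 / 5, which is enough for the
posterior means used here (two independent seeds move π̂ by < 0.05).

Design columns are centered on training means only (no per-SNP variance
scaling) — the GRM uses full standardization; the two uses are deliberately
distinct. Monomorphic-in-training SNPs are excluded from both consistently.
Setting `pi_fixed = 1` disables π sampling and reduces the model to
SNP-BLUP/ridge, which is the closed-form oracle used in testing. GBVs are
ĝ = W_app β̂ with application dosages (fractional imputed dosages allowed)
centered at the stored training means; the intercept is excluded.

π̂ is interpretable as the proportion of SNPs affecting the trait only up
to LD diffusion: with ~0.5 cM marker spacing and strong family LD, a
20-QTL simulated trait yields π̂ ≈ 0.02 at h² = 0.6 and n = 800, but π̂
inflates at lower heritability or shorter chains, as expected when single
QTL signals spread over several linked markers.

## Genomic relatedness (`grm`)

W standardizes each SNP by the training-population mean and divide-by-N
standard deviation (observed-genotype standardization, not 2p/sqrt(2pq));
G = W W′/p. Two identities are then exact and serve as self-checks: every
individual's mean relatedness to the whole training set is 0, and the mean
training diagonal is 1 (the latter is what fixes the divide-by-N choice).
Top-N relatedness of a candidate is the mean of its N largest relationships
to training individuals (self excluded); fraction specs (5%, 25%) resolve
to round(f × n), minimum 1, so with small training sets the top-5% count
can fall below 10 and the usual top-10 ≥ top-5% ordering legitimately
reverses. Family summaries report within-family means and N−1 standard
deviations. LD decay is the mean squared Pearson correlation of dosage
columns per within-chromosome distance bin, plus an adjacent-pair mean.

## Evaluation (`evalsel`)

Accuracy is Pearson r of GBV against the observed score within a family
(families differ in location, so pooling would confound), with the
asymptotic 95% CI tanh(atanh(r) ± 1.96/√(n−3)); Spearman ρ is added when
|Fisher–Pearson skewness| > 1 (the declared cut for "highly skewed"; a
constant vector is flagged by convention). The realized selection
differential takes the k = 50 individuals in each GBV tail (ties broken by
stable order), signs the difference so positive = favourable (defect traits
declare `direction="low"`), and tests it with Welch's two-sample t-test —
"Student's t-test" is under-specified and Welch reduces to it under equal
variances; the directional differential compares the favourable tail to the
family mean (one-sample t). Aggregates (per-family means over all traits
and over the four symmetric traits, per-trait means, global max, mean CI
length) recompute exactly from their member cells, skipping unscored cells.
The √h² attenuation identity cor(ĝ, y) = cor(ĝ, TBV)·√h² — a direct
consequence of y = TBV + independent noise — is checked by construction at
n = 5000, and the no-intercept regression of accuracy on √h² uses the
closed-form slope Σxy/Σx².

`examples.py` carries a published-style per-family accuracy grid (10 traits
× 5 families, two families unscored for pre-harvest dropping) used as the
worked example for the aggregation machinery, together with the associated
design constants (family sizes totalling 1390, 7651 + 178 = 7829 markers,
π values 0.007/0.062/0.319 for three contrasting traits).

## Orchestration (`pipeline`) and problem sizes

`pipeline.run` chains simulate → adjust → relationships → impute → train →
predict → evaluate with one config; all randomness flows from named seeds
(no hidden global state), every stage records SHA-256 output hashes in the
manifest, and two runs with the same config are hash-identical. The
numbered scripts under `analysis/` execute the same stages file-to-file at
the desk-scale preset (5 training families × 100, 2 application families ×
100, 1000 SNPs), which keeps the full analysis under a minute on one core;
the acceptance script uses n = 800/p = 1000 for the sampler-recovery runs
and a 60-offspring family for imputation. These sizes were chosen as the
smallest at which the Monte-Carlo checks are stable; everything scales to
the full default design at proportionally higher cost.

## Known limitations

- The imputation stand-in uses only pedigree + linkage within nuclear
  families; it has no population haplotype library, so candidates without
  genotyped parents cannot be imputed.
- Single-trait models throughout; no multi-trait REML or correlated-trait
  sampler.
- The threshold (probit-liability) ordinal model is deliberately out of
  scope; scores are analysed as continuous, which is adequate at 5
  well-populated classes but biases variance components when scores pile
  into one class.
- EM-REML returns a boundary estimate (σa² = 0) rather than exploring
  negative components; standard errors of variance components are not
  reported.
- A is dense O(n²); pedigrees beyond ~10⁴ individuals need the sparse
  inverse-A route that is intentionally not implemented.
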