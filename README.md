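# orchardgs

Genomic selection for pedigreed, multi-family fruit breeding populations.

Fruit tree breeders cull most seedlings on traits scored before or at first
harvest — productivity and external fruit appearance, recorded on ordinal
1–5 scales. Genomic selection promises to make those culling decisions from
marker data alone: a *training population* (interrelated full-sib families
with both high-density SNP genotypes and historic phenotypes) yields a
prediction model whose genomic breeding values (GBVs)

    ĝ_i = Σ_m w_im β̂_m

are then computed for *application families* — selection candidates typed
only on a cheap low-density panel and imputed to high density through their
pedigree. This package implements that entire analysis as a tested library
plus a sequence of analysis drivers:

- `simdata` — synthetic study populations: interrelated full-sib families,
  gene-dropped SNP haplotypes (Haldane recombination), π-sparse additive
  architectures, ordinal phenotypes from a liability model with year and
  location effects, replicated reference genotypes.
- `pedkin` — pedigree validation and the additive relationship matrix A
  (tabular method).
- `phenoadj` — year/location adjustment from reference genotypes, EM-REML
  variance components (h² = σa²/(σa²+σe²)), animal-model BLUP phenotypes.
- `famimpute` — two-step family imputation: minimum-recombination parent
  phasing, then a 4-state haplotype-origin HMM decoded by forward–backward.
- `bayescpi` — BayesCπ whole-genome regression (Gibbs sampler with a
  point-mass mixture prior; π estimated from the data), GBV prediction.
- `grm` — training-standardized genomic relationships G = W′W/p, top-10 /
  top-5% / top-25% relatedness summaries, LD decay.
- `evalsel` — per-family accuracy with Fisher-z confidence intervals,
  realized and directional selection differentials (Welch t-tests), report
  aggregation, accuracy–√h² regression.
- `pipeline` — one-config orchestration with seeded, hash-verified runs.

See `docs/methods.md` for the models and numerical choices.

## Worked example

The numbered drivers run the full analysis at a desk-scale preset
(5 training families × 100, 2 application families × 100, 1000 SNPs on
5 chromosomes, h² = 0.35, π = 0.05):

```sh
python analysis/01_simulate.py
python analysis/02_adjust_blup.py
python analysis/03_impute.py
python analysis/04_train_predict.py
python analysis/05_relatedness.py
python analysis/06_evaluate.py
```

Output (abridged) from one run:

```
01: training: 500 in 5 families; application: 200 in 2
    score distribution: {1: 318, 2: 268, 3: 267, 4: 279, 5: 331}
02: variance components: sigma_a2=0.929 sigma_e2=0.364 -> h2=0.719
03: low-density panel: 100 SNPs, mean gap 5.26 cM
    AF1: 100 offspring, hard-call concordance 0.944
04: pi_hat = 0.240 -> implied QTL count 222 (simulated: 50)
    predicted GBVs for 200 application individuals; cor(GBV, true BV) = 0.846
06: AF1: n=100 r=0.182 CI [-0.015, 0.366] diff(top20-bottom20)=0.80 (p=0.0654)
    AF2: n=100 r=0.175 CI [-0.022, 0.359] diff(top20-bottom20)=0.80 (p=0.0327)
```

Reading those numbers: the BLUP-scale heritability (0.72) exceeds the
per-record liability h² because adjusted means average over seasons; the
family-HMM imputation recovers ~94% of masked high-density genotypes from a
~5 cM panel; π̂ overestimates the simulated 50 causal SNPs because family
LD diffuses each QTL over linked markers; and although the GBVs track true
breeding values well (r = 0.85), accuracy against single-year *ordinal
scores* is attenuated toward r ≈ √h²·cor(ĝ,TBV) — the tests verify this
attenuation identity explicitly. Selecting the best 20 of 100 candidates by
GBV still shifts the realized phenotype by ≈0.8 score points over the worst
20.

Small summary tables land in `results/` (accuracy.csv, selection.csv,
relatedness.csv, ld_decay.csv, imputation_report.csv); bulky intermediates
go to `scratch/`.

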