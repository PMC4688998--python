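"""Simulate the pedigreed multi-family study population.

Generates the desk-scale preset — 5 training full-sib families of 100 from
an interrelated parent pool, 2 application families of 100 sharing parents
with training, 5 chromosomes x 200 SNPs (1000 markers, ~0.5 cM spacing) —
with a pi-sparse additive trait (h2 = 0.35) scored 1-5 across years and
locations, plus 29 replicated reference genotypes linking the environments.
Writes the raw data files and the simulation truth for the later steps.
"""

import importlib
import json

paths = importlib.import_module("00_paths")

from orchardgs import simdata  # noqa: E402

cfg = simdata.small_preset()
pop = simdata.simulate_population(cfg)
fped = pop["fped"]

fped.pedigree.write_csv(paths.SCRATCH / "pedigree.csv")
pop["map"].write_tsv(paths.SCRATCH / "map.tsv")
pop["genotypes"].write_tsv(paths.SCRATCH / "genotypes.tsv")
pop["phenotypes"].to_csv(paths.SCRATCH / "phenotypes.csv", index=False)
pop["architectures"][0].to_json(paths.SCRATCH / "truth.json")
with open(paths.SCRATCH / "families.json", "w") as fh:
    json.dump({"training": fped.training_families,
               "application": fped.application_families,
               "parents": fped.family_parents}, fh)

pheno = pop["phenotypes"]
print(f"pedigree: {len(fped.pedigree)} individuals "
      f"({len(fped.pedigree.founders)} founders)")
print(f"training: {len(fped.training_ids)} in {len(fped.training_families)} families; "
      f"application: {len(fped.application_ids)} in {len(fped.application_families)}")
print(f"markers: {pop['map'].n_snps} on {cfg.n_chromosomes} chromosomes")
print(f"phenotype records: {len(pheno)} "
      f"({pheno['is_reference'].sum()} reference records)")
print("score distribution:",
      pheno.loc[~pheno.is_reference, "score"].value_counts().sort_index().to_dict())
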