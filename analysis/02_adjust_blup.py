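"""Adjust ordinal scores for year/location and compute BLUP phenotypes.

Fixed year and location effects come from the replicated reference
genotypes alone (they are the only individuals scored in every
environment); adjusted per-individual means then feed the animal model,
EM-REML estimates the additive and residual variances, and Henderson's
equations give each training individual its genotypic BLUP — the phenotype
the prediction model is trained on.
"""

import importlib
import json

import pandas as pd

paths = importlib.import_module("00_paths")

from orchardgs import pedkin, phenoadj  # noqa: E402

ped = pedkin.Pedigree.read_csv(paths.SCRATCH / "pedigree.csv")
ped = pedkin.sort_and_validate(ped)
A = pedkin.build_a_matrix(ped)
pedkin.write_a_matrix(A, paths.SCRATCH / "a_matrix.tsv")

pheno = pd.read_csv(paths.SCRATCH / "phenotypes.csv")
with open(paths.SCRATCH / "families.json") as fh:
    families = json.load(fh)
training_ids = [i for fam in families["training"].values() for i in fam]

blup, vc, eff = phenoadj.blup_phenotypes(pheno, A, "trait1",
                                         training_ids=training_ids)
blup.rename("blup").to_frame().rename_axis("id").to_csv(
    paths.SCRATCH / "blup.csv")
with open(paths.RESULTS / "variance_components.json", "w") as fh:
    json.dump({"trait1": {"sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
                          "h2": vc.h2, "converged": vc.converged,
                          "year_effects": {str(k): v for k, v in eff.year.items()},
                          "location_effects": {str(k): v for k, v
                                               in eff.location.items()}}},
              fh, indent=2)

print(f"estimated year effects: { {int(k): round(v, 3) for k, v in eff.year.items()} }")
print(f"estimated location effects: "
      f"{ {k: round(v, 3) for k, v in eff.location.items()} }")
print(f"variance components: sigma_a2={vc.sigma_a2:.3f} "
      f"sigma_e2={vc.sigma_e2:.3f} -> h2={vc.h2:.3f} "
      f"(converged={vc.converged})")
print(f"BLUP phenotypes for {len(blup)} training individuals, "
      f"range [{blup.min():.2f}, {blup.max():.2f}]")
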