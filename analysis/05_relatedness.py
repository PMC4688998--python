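"""Genomic and pedigree relatedness of application families to training.

Standardizes dosages with training means/SDs, builds G = W'W/p, and
summarizes each application family by the mean of its members' top-10,
top-5% and top-25% relatedness to the training population, alongside the
pedigree-based expectation from the A matrix.  Also reports LD decay of the
training genotypes by map distance.
"""

import importlib
import json

import numpy as np
import pandas as pd

paths = importlib.import_module("00_paths")

from orchardgs import grm, pedkin, simdata  # noqa: E402

gmap = simdata.GeneticMap.read_tsv(paths.SCRATCH / "map.tsv")
geno = simdata.GenotypeMatrix.read_tsv(paths.SCRATCH / "genotypes.tsv", gmap)
A = pedkin.read_a_matrix(paths.SCRATCH / "a_matrix.tsv")
with open(paths.SCRATCH / "families.json") as fh:
    families = json.load(fh)
training_ids = [i for fam in families["training"].values() for i in fam]

std = grm.standardize(geno.to_frame(), training_ids)
G = grm.compute_g(std.W)
print(f"G over {G.shape[0]} individuals from {std.W.shape[1]} SNPs "
      f"({len(std.excluded)} monomorphic in training excluded)")

summary = grm.family_relatedness_summary(G, families["application"],
                                         training_ids)
ped_rel = {fam: pedkin.pedigree_family_relatedness(A, members, training_ids)
           for fam, members in families["application"].items()}
ped_rows = pd.DataFrame(
    [{"family": f, "measure": "pedigree", "mean": v, "sd": np.nan,
      "n": len(families["application"][f])} for f, v in ped_rel.items()])
table = pd.concat([summary, ped_rows], ignore_index=True)
table.to_csv(paths.RESULTS / "relatedness.csv", index=False)
print(table.pivot(index="measure", columns="family", values="mean").round(3))

ld = grm.ld_decay(std.W.loc[training_ids], gmap,
                  bins=((0, 1), (1, 5), (5, 20), (20, 100)))
ld.to_csv(paths.RESULTS / "ld_decay.csv", index=False)
print("training LD decay (mean r^2 per distance bin):")
print(ld.to_string(index=False))
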