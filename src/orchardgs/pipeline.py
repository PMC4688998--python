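"""End-to-end orchestration: simulate -> adjust -> train -> impute -> predict -> evaluate.

The runner executes the full genomic-selection analysis on a synthetic
population with one config and per-stage seeds, returning every intermediate
object plus a manifest (stage -> seed, wall time, output hashes) so a rerun
with identical settings is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayescpi, evalsel, famimpute, grm, pedkin, phenoadj, simdata

log = logging.getLogger("orchardgs")


@dataclass
class RunConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.small_preset)
    chain: bayescpi.ChainConfig = field(
        default_factory=lambda: bayescpi.ChainConfig(iterations=6000, burn_in=1000,
                                                     thinning=5))
    n_panel_snps: int = 100  # low-density panel size for application families
    selection_k: int = 20
    trait_directions: dict = field(default_factory=dict)  # trait -> high/low
    stages: tuple = ("simulate", "adjust", "relationships", "impute",
                     "train", "predict", "evaluate")
    out_dir: str | None = None
    seed: int = 2015

    def direction(self, trait: str) -> str:
        return self.trait_directions.get(trait, "high")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Top-level keys mirror the dataclass fields; the nested ``sim`` and
        ``chain`` mappings override fields of the small-preset SimConfig and
        the default ChainConfig.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simdata.small_preset()
        for key, val in (raw.pop("sim", {}) or {}).items():
            if not hasattr(sim, key):
                raise ValueError(f"unknown sim config field {key!r}")
            setattr(sim, key, tuple(val) if isinstance(val, list) else val)
        sim.validate()
        chain = bayescpi.ChainConfig(**(raw.pop("chain", {}) or {}))
        chain.validate()
        known = {f for f in cls.__dataclass_fields__} - {"sim", "chain"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run config fields {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim, chain=chain, **raw)


def _hash_array(arr) -> str:
    a = np.ascontiguousarray(np.asarray(arr, dtype=float))
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def validate_inputs(fped, genotypes, phenotypes, gmap) -> list:
    """Cross-file consistency report: orphan ids, map order, duplicates.

    Returns a machine-readable list of {class, detail} issues; empty when
    everything is consistent.
    """
    issues = []
    ped_ids = set(fped.pedigree.ids)
    for iid in genotypes.ids:
        if iid not in ped_ids:
            issues.append({"class": "orphan-id",
                           "detail": f"genotyped individual {iid} absent from pedigree"})
    non_ref = phenotypes[~phenotypes["is_reference"]]
    for iid in non_ref["id"].unique():
        if iid not in ped_ids:
            issues.append({"class": "orphan-id",
                           "detail": f"phenotyped individual {iid} absent from pedigree"})
    for chrom, _, pos in gmap.chrom_slices():
        if np.any(np.diff(pos) < 0):
            issues.append({"class": "map-order",
                           "detail": f"chromosome {chrom} positions not sorted"})
    snps = gmap.snps
    if len(set(snps)) != len(snps):
        issues.append({"class": "duplicate-snp", "detail": "duplicated SNP names"})
    bad = non_ref[(non_ref["score"] < 1) | (non_ref["score"] > 5)]
    if len(bad):
        issues.append({"class": "score-range",
                       "detail": f"{len(bad)} scores outside 1..5"})
    return issues


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns all stage outputs plus a
    ``manifest``.  Fails fast with the failing stage named."""
    state: dict = {"manifest": {}}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def record(stage, t0, hashes):
        state["manifest"][stage] = {
            "seed": config.seed,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "hashes": hashes,
        }

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                pop = simdata.simulate_population(config.sim)
                state["pop"] = pop
                issues = validate_inputs(pop["fped"], pop["genotypes"],
                                         pop["phenotypes"], pop["map"])
                state["validation"] = issues
                if issues:
                    log.warning("validation issues: %s", issues)
                record(stage, t0, {
                    "genotypes": _hash_array(pop["genotypes"].dosages),
                    "phenotypes": _hash_frame(pop["phenotypes"]),
                })
                if out_dir:
                    pop["fped"].pedigree.write_csv(out_dir / "pedigree.csv")
                    pop["map"].write_tsv(out_dir / "map.tsv")
                    pop["phenotypes"].to_csv(out_dir / "phenotypes.csv", index=False)

            elif stage == "adjust":
                pop = state["pop"]
                fped = pop["fped"]
                A = state.get("A")
                if A is None:
                    A = pedkin.build_a_matrix(fped.pedigree)
                    state["A"] = A
                blups, vcs = {}, {}
                for t, arch in enumerate(pop["architectures"]):
                    trait = f"trait{t + 1}"
                    blup, vc, eff = phenoadj.blup_phenotypes(
                        pop["phenotypes"], A, trait,
                        training_ids=fped.training_ids)
                    blups[trait] = blup
                    vcs[trait] = vc
                    if not vc.converged:
                        log.warning("REML did not converge for %s", trait)
                state["blups"] = blups
                state["variance_components"] = vcs
                record(stage, t0, {t: _hash_array(b.to_numpy())
                                   for t, b in blups.items()})

            elif stage == "relationships":
                pop = state["pop"]
                fped = pop["fped"]
                if "A" not in state:
                    state["A"] = pedkin.build_a_matrix(fped.pedigree)
                X = pop["genotypes"].to_frame()
                std = grm.standardize(X, fped.training_ids)
                G = grm.compute_g(std.W)
                state["G"] = G
                state["relatedness"] = grm.family_relatedness_summary(
                    G, fped.application_families, fped.training_ids)
                state["pedigree_relatedness"] = {
                    fam: pedkin.pedigree_family_relatedness(
                        state["A"], members, fped.training_ids)
                    for fam, members in fped.application_families.items()}
                record(stage, t0, {"G": _hash_array(G.to_numpy())})

            elif stage == "impute":
                pop = state["pop"]
                fped = pop["fped"]
                geno = pop["genotypes"]
                panel = simdata.select_panel(pop["map"], config.n_panel_snps)
                state["panel"] = panel
                imputed = {}
                rows = []
                for fam, members in fped.application_families.items():
                    sire, dam = fped.family_parents[fam]
                    fam_ld = simdata.mask_to_low_density(geno.subset(members), panel)
                    imp = famimpute.impute_family(
                        fam_ld, geno.row(sire), geno.row(dam),
                        hd_offspring=geno.subset(members[: min(5, len(members))]).dosages)
                    imputed[fam] = imp
                    truth = geno.subset(members).dosages
                    mask = np.isnan(fam_ld.dosages)
                    conc = float(np.mean(np.round(imp.dosages[mask]) == truth[mask]))
                    rows.append((fam, conc))
                state["imputed"] = imputed
                state["imputation_report"] = pd.DataFrame(
                    rows, columns=["family", "masked_concordance"])
                record(stage, t0, {f: _hash_array(g.dosages)
                                   for f, g in imputed.items()})

            elif stage == "train":
                pop = state["pop"]
                fped = pop["fped"]
                X = pop["genotypes"].to_frame().loc[fped.training_ids]
                design = bayescpi.DesignMatrix.from_dosages(X)
                models = {}
                for trait, blup in state["blups"].items():
                    chain = bayescpi.ChainConfig(**{**asdict(config.chain),
                                                    "seed": config.chain.seed})
                    models[trait] = bayescpi.fit_bayescpi(design, blup, chain)
                state["models"] = models
                record(stage, t0, {t: _hash_array(m.snp_effects.to_numpy())
                                   for t, m in models.items()})

            elif stage == "predict":
                pop = state["pop"]
                fped = pop["fped"]
                frames = []
                for fam, imp in state["imputed"].items():
                    Xa = imp.to_frame()
                    for trait, model in state["models"].items():
                        g = bayescpi.predict_gbv(model, Xa, trait)
                        g["family"] = fam
                        frames.append(g)
                state["gbv"] = pd.concat(frames, ignore_index=True)
                record(stage, t0, {"gbv": _hash_frame(state["gbv"])})

            elif stage == "evaluate":
                pop = state["pop"]
                fped = pop["fped"]
                pheno = pop["phenotypes"]
                app = pheno[pheno["id"].isin(fped.application_ids)]
                acc_rows, sel_rows = [], []
                for (fam, trait), grp in state["gbv"].groupby(["family", "trait"]):
                    scores = app[app["trait"] == trait].set_index("id")["score"]
                    ids = [i for i in grp["id"] if i in scores.index]
                    g = grp.set_index("id").loc[ids, "gbv"]
                    y = scores.loc[ids]
                    skew = evalsel.skewness_flag(y) if len(y) >= 10 else False
                    rec = evalsel.accuracy(g, y, fam, trait, skew_flag=skew)
                    acc_rows.append({"family": fam, "trait": trait, "n": rec.n,
                                     "r": rec.pearson_r, "ci_low": rec.ci_low,
                                     "ci_high": rec.ci_high,
                                     "ci_length": rec.ci_length,
                                     "spearman": rec.spearman_rho})
                    k = min(config.selection_k, len(ids) // 2)
                    if k >= 2:
                        sd = evalsel.selection_differential(
                            g.to_numpy(), y.to_numpy(), k=k,
                            direction=config.direction(trait),
                            family=fam, trait=trait)
                        sel_rows.append(asdict(sd))
                acc = pd.DataFrame(acc_rows)
                state["accuracy"] = acc
                state["selection"] = pd.DataFrame(sel_rows)
                state["report"] = evalsel.aggregate_report(
                    acc, symmetric_traits=tuple(acc["trait"].unique()))
                vcs = state.get("variance_components", {})
                if vcs:
                    trait_means = acc.groupby("trait")["r"].mean()
                    h2s = [vcs[t].h2 for t in trait_means.index if t in vcs]
                    if h2s and any(h > 0 for h in h2s):
                        state["h2_slope"] = evalsel.accuracy_h2_regression(
                            trait_means[: len(h2s)], h2s)
                record(stage, t0, {"accuracy": _hash_frame(acc)})
                if out_dir:
                    acc.to_csv(out_dir / "accuracy.csv", index=False)
                    state["selection"].to_csv(out_dir / "selection.csv", index=False)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done in %.2fs", stage,
                 state["manifest"][stage]["wall_time_s"])

    if out_dir:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(state["manifest"], fh, indent=2)
    return state
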