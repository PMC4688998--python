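"""Synthetic pedigreed multi-family populations with genotypes and phenotypes.

The generator emulates the data structure of a pedigreed genomic-selection
study in an outbred fruit crop: ~20 interrelated training full-sib families
(total near 1000 individuals) whose parents share common ancestors, plus a
handful of large application full-sib families that reuse a fraction of the
training parents.  SNP haplotypes are dropped through the pedigree with
Haldane (no-interference) recombination; founder haplotypes are drawn in
linkage equilibrium, so all LD is pedigree-generated.  Phenotypes follow an
additive liability model with year and location offsets, discretised to an
ordinal 1-5 score through fixed thresholds; replicated reference genotypes
(clones scored at every location) tie the environments together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedkin import UNKNOWN, Pedigree

# liability-scale thresholds giving five equal ordinal classes under N(0,1)
EQUAL_MASS_THRESHOLDS = (-0.8416, -0.2533, 0.2533, 0.8416)
# "skewed" preset: most mass in score 1, emulating defect traits
# (fruit cracking / pre-harvest dropping style distributions)
SKEWED_THRESHOLDS = (1.0364, 1.6449, 2.0537, 2.3263)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the multi-family apple design the package analyses:
    20 training full-sib families (~980 individuals) from 24 interrelated
    parents, 5 application families with sizes 662/172/269/109/178, a
    17-chromosome genome of ~1350 cM, and ordinal 1-5 scores from an
    additive liability with trait heritability in the 0.03-0.67 range.
    """

    n_founders: int = 12
    n_parent_pool: int = 24
    n_training_families: int = 20
    training_family_sizes: tuple = tuple([49] * 20)
    n_application_families: int = 5
    application_family_sizes: tuple = (662, 172, 269, 109, 178)
    shared_parent_fraction: float = 0.5
    n_chromosomes: int = 17
    markers_per_chromosome: int = 460
    chromosome_length: float = 79.4  # cM
    founder_freq_range: tuple = (0.1, 0.9)
    pi_true: float = 0.05
    h2_target: float = 0.35
    n_traits: int = 1
    year_effects: dict = field(default_factory=lambda: {1: 0.0, 2: 0.3, 3: -0.3})
    location_effects: dict = field(
        default_factory=lambda: {"L1": 0.0, "L2": 0.5, "L3": -0.5, "L4": 0.25}
    )
    n_reference_genotypes: int = 29
    ordinal_thresholds: tuple = EQUAL_MASS_THRESHOLDS
    seed: int = 2015

    def validate(self) -> None:
        if any(s <= 0 for s in self.training_family_sizes):
            raise ValueError("training family sizes must be positive")
        if any(s <= 0 for s in self.application_family_sizes):
            raise ValueError("application family sizes must be positive")
        if len(self.training_family_sizes) != self.n_training_families:
            raise ValueError("training_family_sizes length != n_training_families")
        if len(self.application_family_sizes) != self.n_application_families:
            raise ValueError("application_family_sizes length != n_application_families")
        if not (0.0 < self.pi_true <= 1.0):
            raise ValueError("pi_true must be in (0, 1]")
        h2s = np.atleast_1d(np.asarray(self.h2_target, dtype=float))
        if np.any((h2s < 0) | (h2s > 1)):
            raise ValueError("h2_target must be in [0, 1]")
        th = np.asarray(self.ordinal_thresholds, dtype=float)
        if th.size != 4 or np.any(np.diff(th) <= 0):
            raise ValueError("ordinal_thresholds must be 4 strictly increasing cut points")
        if not (0.0 <= self.shared_parent_fraction <= 1.0):
            raise ValueError("shared_parent_fraction must be in [0, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")

    def h2_list(self) -> list:
        h2s = np.atleast_1d(np.asarray(self.h2_target, dtype=float))
        if h2s.size == 1 and self.n_traits > 1:
            h2s = np.repeat(h2s, self.n_traits)
        if h2s.size != self.n_traits:
            raise ValueError("h2_target length must match n_traits")
        return [float(h) for h in h2s]


def small_preset() -> SimConfig:
    """Reduced desk-scale preset: 5 training families x 100, 2 application
    families x 100, 5 chromosomes x 200 markers (1000 SNPs)."""
    return SimConfig(
        n_founders=10,
        n_parent_pool=8,
        n_training_families=5,
        training_family_sizes=(100,) * 5,
        n_application_families=2,
        application_family_sizes=(100, 100),
        n_chromosomes=5,
        markers_per_chromosome=200,
        chromosome_length=100.0,
    )


class GeneticMap:
    """Marker map: snp name, chromosome, position in centimorgans."""

    def __init__(self, frame: pd.DataFrame):
        required = {"snp", "chrom", "pos_cM"}
        if frame.empty or not required.issubset(frame.columns):
            raise ValueError("map needs non-empty columns snp, chrom, pos_cM")
        for _, grp in frame.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_cM"].to_numpy()) < 0):
                raise ValueError("map positions must be non-decreasing within chromosome")
        self.frame = frame.reset_index(drop=True)

    @property
    def snps(self) -> list:
        return self.frame["snp"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    def chrom_slices(self) -> list:
        """(chrom, index array, positions array) per chromosome, in file order."""
        out = []
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            out.append((chrom, grp.index.to_numpy(), grp["pos_cM"].to_numpy()))
        return out

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))


def make_genetic_map(n_chromosomes: int, markers_per_chromosome: int,
                     chromosome_length: float) -> GeneticMap:
    """Evenly spaced markers on each chromosome, positions 0..length cM."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        if markers_per_chromosome == 1:
            pos = np.array([0.0])
        else:
            pos = np.linspace(0.0, chromosome_length, markers_per_chromosome)
        for j, p in enumerate(pos):
            rows.append((f"chr{c:02d}_snp{j + 1:04d}", c, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["snp", "chrom", "pos_cM"]))


class GenotypeMatrix:
    """Individuals x SNPs dosages with an attached map; optionally phased.

    ``dosages`` is float with NaN for missing.  When built by gene dropping,
    ``haplotypes`` holds the phased alleles (n_individuals, n_snps, 2).
    """

    def __init__(self, ids, gmap: GeneticMap, dosages: np.ndarray,
                 haplotypes: np.ndarray | None = None):
        self.ids = list(ids)
        self.map = gmap
        self.dosages = np.asarray(dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), gmap.n_snps):
            raise ValueError("dosage matrix shape does not match ids x map")
        self.haplotypes = haplotypes
        self._row = {iid: k for k, iid in enumerate(self.ids)}

    def row(self, iid) -> np.ndarray:
        return self.dosages[self._row[iid]]

    def subset(self, ids) -> "GenotypeMatrix":
        rows = [self._row[i] for i in ids]
        hap = self.haplotypes[rows] if self.haplotypes is not None else None
        return GenotypeMatrix(ids, self.map, self.dosages[rows].copy(), hap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.map.snps)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.4g")

    @classmethod
    def read_tsv(cls, path, gmap: GeneticMap) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id", na_values="NA")
        df = df[gmap.snps]
        return cls(df.index.tolist(), gmap, df.to_numpy(dtype=float))


@dataclass
class FamilyPedigree:
    """Pedigree plus the family structure that produced it."""

    pedigree: Pedigree
    training_families: dict  # family name -> list of offspring ids
    application_families: dict
    family_parents: dict  # family name -> (sire, dam)

    @property
    def training_ids(self) -> list:
        return [i for fam in self.training_families.values() for i in fam]

    @property
    def application_ids(self) -> list:
        return [i for fam in self.application_families.values() for i in fam]

    @property
    def training_parents(self) -> list:
        seen = []
        for name in self.training_families:
            for p in self.family_parents[name]:
                if p not in seen:
                    seen.append(p)
        return seen


@dataclass
class TrueArchitecture:
    """Simulation ground truth: which SNPs are causal and their effects."""

    causal_indices: np.ndarray
    causal_effects: np.ndarray  # aligned with causal_indices
    effects: np.ndarray  # full-length vector, zero off the causal set
    true_breeding_values: pd.Series  # indexed by individual id
    h2_target: float

    def to_json(self, path) -> None:
        payload = {
            "h2_target": self.h2_target,
            "causal_indices": self.causal_indices.tolist(),
            "causal_effects": self.causal_effects.tolist(),
            "true_breeding_values": {k: float(v) for k, v in self.true_breeding_values.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> FamilyPedigree:
    """Build the multi-family pedigree.

    Founders are unrelated individuals with unknown parents.  A pool of
    parents is created by crossing founders (so parents share ancestors),
    training families are crosses of pool members, and application-family
    parents reuse training parents at exactly
    ``round(shared_parent_fraction * n_application_parents)`` slots; the
    remaining application parents are fresh crosses of founders.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    ped = Pedigree()
    founders = [f"F{k + 1:03d}" for k in range(config.n_founders)]
    for f in founders:
        ped.add(f)

    def cross_of_founders(name):
        s, d = rng.choice(config.n_founders, size=2, replace=False)
        ped.add(name, founders[s], founders[d])
        return name

    if config.n_parent_pool > 0:
        pool = [cross_of_founders(f"P{k + 1:03d}") for k in range(config.n_parent_pool)]
    else:  # cross the founders directly
        pool = list(founders)
    if len(pool) < 2:
        raise ValueError("parent pool must contain at least 2 individuals")

    training_families: dict = {}
    family_parents: dict = {}
    for k, size in enumerate(config.training_family_sizes):
        name = f"TF{k + 1:02d}"
        s, d = rng.choice(len(pool), size=2, replace=False)
        sire, dam = pool[s], pool[d]
        kids = [f"{name}_{j + 1:04d}" for j in range(size)]
        for kid in kids:
            ped.add(kid, sire, dam)
        training_families[name] = kids
        family_parents[name] = (sire, dam)

    training_parents = []
    for name in training_families:
        for p in family_parents[name]:
            if p not in training_parents:
                training_parents.append(p)

    n_app_parents = 2 * config.n_application_families
    n_shared = int(round(config.shared_parent_fraction * n_app_parents))
    shared_flags = np.zeros(n_app_parents, dtype=bool)
    shared_flags[rng.choice(n_app_parents, size=n_shared, replace=False)] = True

    application_families: dict = {}
    slot = 0
    n_new = 0
    for k, size in enumerate(config.application_family_sizes):
        name = f"AF{k + 1}"
        pair = []
        for _ in range(2):
            if shared_flags[slot] and training_parents:
                pair.append(training_parents[int(rng.integers(len(training_parents)))])
            else:
                n_new += 1
                pair.append(cross_of_founders(f"Q{n_new:03d}"))
            slot += 1
        if pair[0] == pair[1]:  # a full-sib family needs two distinct parents
            n_new += 1
            pair[1] = cross_of_founders(f"Q{n_new:03d}")
        sire, dam = pair
        kids = [f"{name}_{j + 1:04d}" for j in range(size)]
        for kid in kids:
            ped.add(kid, sire, dam)
        application_families[name] = kids
        family_parents[name] = (sire, dam)

    return FamilyPedigree(ped, training_families, application_families, family_parents)


def _meiosis(parent_hap: np.ndarray, chrom_slices, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's phased pair (n_snps, 2) -> (n_snps,)."""
    gamete = np.empty(parent_hap.shape[0], dtype=np.int8)
    for _, idx, pos in chrom_slices:
        d = np.diff(pos)
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))  # Haldane, d in cM
        cross = rng.random(r.size) < r
        start = int(rng.integers(2))
        which = (start + np.concatenate(([0], np.cumsum(cross)))) % 2
        gamete[idx] = parent_hap[idx, :][np.arange(idx.size), which]
    return gamete


def gene_drop(fped: FamilyPedigree | Pedigree, gmap: GeneticMap,
              founder_freqs: np.ndarray, seed: int) -> GenotypeMatrix:
    """Drop phased haplotypes through the pedigree with Haldane recombination.

    Founder haplotype alleles are independent Bernoulli(founder_freqs) per
    SNP (linkage equilibrium); every descendant receives one recombinant
    gamete from each parent, with no crossover interference.
    """
    ped = fped.pedigree if isinstance(fped, FamilyPedigree) else fped
    freqs = np.asarray(founder_freqs, dtype=float)
    if freqs.size == 1:
        freqs = np.repeat(freqs, gmap.n_snps)
    if freqs.size != gmap.n_snps:
        raise ValueError("founder_freqs length must match the map")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("founder frequencies must be in (0, 1)")

    rng = np.random.default_rng(seed)
    slices = gmap.chrom_slices()
    n = len(ped)
    hap = np.zeros((n, gmap.n_snps, 2), dtype=np.int8)
    row = {iid: k for k, iid in enumerate(ped.ids)}
    for iid in ped.ids:
        i = row[iid]
        s, d = ped.parents(iid)
        for h, parent in enumerate((s, d)):
            if parent == UNKNOWN:
                hap[i, :, h] = rng.random(gmap.n_snps) < freqs
            else:
                if parent not in row:
                    raise KeyError(f"unknown parent id {parent!r}")
                hap[i, :, h] = _meiosis(hap[row[parent]], slices, rng)
    dosages = hap.sum(axis=2).astype(float)
    return GenotypeMatrix(ped.ids, gmap, dosages, haplotypes=hap)


def assign_architecture(genotypes: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        h2: float | None = None) -> TrueArchitecture:
    """Sample a pi-sparse additive architecture and compute breeding values.

    Causal SNPs are a uniform draw of round(pi_true * n_SNPs) markers;
    effects are zero-mean normal rescaled so the realized variance of the
    true breeding values (over all individuals, centered dosages) equals the
    additive variance implied by ``h2`` on a unit-total-variance liability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    h2 = float(config.h2_list()[0]) if h2 is None else float(h2)
    p = genotypes.map.n_snps
    n_causal = int(round(config.pi_true * p))
    if n_causal > p:
        raise ValueError("fewer SNPs than round(pi_true * n_SNPs)")
    n_causal = max(n_causal, 1) if config.pi_true > 0 else 0
    causal = np.sort(rng.choice(p, size=n_causal, replace=False))
    effects = np.zeros(p)
    raw = rng.standard_normal(n_causal)
    centered = genotypes.dosages - genotypes.dosages.mean(axis=0)
    if h2 > 0:
        tbv_raw = centered[:, causal] @ raw
        v = tbv_raw.var()
        scale = np.sqrt(h2 / v) if v > 0 else 0.0
        effects[causal] = raw * scale
    tbv = pd.Series(centered @ effects, index=genotypes.ids)
    return TrueArchitecture(causal, effects[causal], effects, tbv, h2)


def simulate_phenotypes(architecture: TrueArchitecture, fped: FamilyPedigree,
                        config: SimConfig, seed: int,
                        trait: str = "trait1") -> tuple[pd.DataFrame, list]:
    """Ordinal 1-5 phenotype records from the liability model.

    liability = TBV + year effect + location effect + N(0, sigma_e2) with
    sigma_e2 chosen so var(TBV) / (var(TBV) + sigma_e2) = h2_target; the
    score is 1 + the number of thresholds below the liability.  Training
    families are each scored at one location in >= 2 years; application
    families at one location in a single (final) year; reference genotypes
    (clones, no pedigree links) are scored in every location x year cell.

    Returns the record table (id, trait, year, location, score, is_reference,
    liability) and the list of reference-genotype ids.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    th = np.asarray(config.ordinal_thresholds, dtype=float)
    years = sorted(config.year_effects)
    locations = sorted(config.location_effects)
    h2 = architecture.h2_target
    var_tbv = float(architecture.true_breeding_values.var()) if h2 > 0 else 0.0
    sigma_e2 = var_tbv * (1.0 - h2) / h2 if h2 > 0 else 1.0

    records = []

    def emit(iid, g, year, loc, is_ref):
        liab = (g + config.year_effects[year] + config.location_effects[loc]
                + rng.normal(0.0, np.sqrt(sigma_e2)))
        score = 1 + int(np.sum(th < liab))
        records.append((iid, trait, year, loc, score, is_ref, liab))

    fam_loc = {}
    for k, name in enumerate(fped.training_families):
        fam_loc[name] = locations[k % len(locations)]
    for k, name in enumerate(fped.application_families):
        fam_loc[name] = locations[k % min(2, len(locations))]

    tbv = architecture.true_breeding_values
    for name, members in fped.training_families.items():
        loc = fam_loc[name]
        for iid in members:
            n_years = 2 + int(rng.integers(0, max(1, len(years) - 1)))
            for year in rng.choice(years, size=min(n_years, len(years)), replace=False):
                emit(iid, tbv[iid], int(year), loc, False)
    last_year = years[-1]
    for name, members in fped.application_families.items():
        loc = fam_loc[name]
        for iid in members:
            emit(iid, tbv[iid], last_year, loc, False)

    ref_ids = [f"REF{k + 1:02d}" for k in range(config.n_reference_genotypes)]
    ref_g = rng.normal(0.0, np.sqrt(var_tbv) if var_tbv > 0 else 1.0,
                       size=len(ref_ids))
    for iid, g in zip(ref_ids, ref_g):
        for year in years:
            for loc in locations:
                emit(iid, g, year, loc, True)

    table = pd.DataFrame(
        records,
        columns=["id", "trait", "year", "location", "score", "is_reference", "liability"],
    )
    return table, ref_ids


def mask_to_low_density(genotypes: GenotypeMatrix, target_snp_set) -> GenotypeMatrix:
    """Set every SNP outside the target panel to missing (NaN)."""
    targets = set(target_snp_set)
    if not targets:
        raise ValueError("target SNP set is empty")
    unknown = targets - set(genotypes.map.snps)
    if unknown:
        raise ValueError(f"target SNPs not on the map: {sorted(unknown)[:5]}")
    keep = np.array([s in targets for s in genotypes.map.snps])
    dos = genotypes.dosages.copy()
    dos[:, ~keep] = np.nan
    return GenotypeMatrix(genotypes.ids, genotypes.map, dos)


def mean_panel_gap(gmap: GeneticMap, target_snp_set) -> float:
    """Mean within-chromosome gap (cM) between adjacent panel markers."""
    targets = set(target_snp_set)
    gaps = []
    for _, idx, pos in gmap.chrom_slices():
        names = [gmap.snps[i] for i in idx]
        sel = pos[[k for k, s in enumerate(names) if s in targets]]
        if sel.size >= 2:
            gaps.extend(np.diff(np.sort(sel)))
    return float(np.mean(gaps)) if gaps else float("nan")


def select_panel(gmap: GeneticMap, n_panel: int, rng=None) -> list:
    """Pick an approximately evenly spaced low-density panel of n_panel SNPs,
    allocated to chromosomes proportionally to marker counts."""
    slices = gmap.chrom_slices()
    total = gmap.n_snps
    chosen = []
    for _, idx, _ in slices:
        k = max(1, int(round(n_panel * idx.size / total)))
        take = np.unique(np.linspace(0, idx.size - 1, k).round().astype(int))
        chosen.extend(gmap.snps[i] for i in idx[take])
    return chosen


def simulate_population(config: SimConfig):
    """End-to-end convenience: pedigree, genotypes, architectures, phenotypes.

    Returns a dict with keys ``fped``, ``map``, ``genotypes``,
    ``architectures`` (per trait), ``phenotypes`` (one table, all traits),
    ``reference_ids``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fped = generate_pedigree(config, rng)
    gmap = make_genetic_map(config.n_chromosomes, config.markers_per_chromosome,
                            config.chromosome_length)
    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=gmap.n_snps)
    geno = gene_drop(fped, gmap, freqs, seed=int(rng.integers(2**31)))
    archs, tables = [], []
    for t, h2 in enumerate(config.h2_list()):
        arch = assign_architecture(geno, config, rng, h2=h2)
        pheno, ref_ids = simulate_phenotypes(arch, fped, config,
                                             seed=int(rng.integers(2**31)),
                                             trait=f"trait{t + 1}")
        archs.append(arch)
        tables.append(pheno)
    phenotypes = pd.concat(tables, ignore_index=True)
    return {
        "fped": fped,
        "map": gmap,
        "genotypes": geno,
        "architectures": archs,
        "phenotypes": phenotypes,
        "reference_ids": ref_ids,
    }
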