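"""Low-density to high-density genotype imputation within full-sib families.

Application individuals typed on a sparse panel are imputed to the full
marker set in two steps: (1) phase each high-density parent into two
haplotypes using its informative offspring (greedy chaining of adjacent
heterozygous markers by a minimum-recombination vote); (2) for every
offspring, decode a 4-state hidden path over the markers — which paternal
and which maternal haplotype the offspring carries — by forward-backward,
with Haldane transition probabilities per parent between adjacent markers
and a genotyping-error emission.  Untyped markers are filled with the
posterior expected dosage implied by the decoded origins and the parental
haplotypes.  Observed genotypes always pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import GeneticMap, GenotypeMatrix

DEFAULT_ERROR_RATE = 0.01


class MendelianError(ValueError):
    """Raised when parent/offspring genotypes conflict beyond tolerance."""


@dataclass
class ParentalHaplotypes:
    """Two haplotype allele-probability vectors for one parent.

    ``p_allele1`` has shape (n_snps, 2): column h is the probability that
    haplotype h carries allele 1.  Homozygous markers are deterministic,
    phased heterozygous markers are 0/1, unphased heterozygous markers are
    0.5 on both haplotypes.  ``phased`` flags markers whose heterozygous
    phase was resolved.
    """

    p_allele1: np.ndarray
    phased: np.ndarray  # bool per SNP
    dosage: np.ndarray


def _transmitted_alleles(parent_dos, mate_dos, off_dos):
    """Allele transmitted by `parent` to each offspring at each SNP.

    Returns (k, p) float array with 0/1 where determined, NaN otherwise.
    Determined when the offspring dosage minus every possible mate
    contribution leaves a single feasible value in {0, 1}.
    """
    k, p = off_dos.shape
    out = np.full((k, p), np.nan)
    mate_half = mate_dos / 2.0
    mate_het = mate_dos == 1
    for cand_mate in (0.0, 1.0):
        # feasible mate transmissions: hom -> dosage/2 only; het -> 0 or 1
        feas = np.where(mate_het, True, mate_half == cand_mate)
        t = off_dos - cand_mate
        ok = feas & (t >= 0) & (t <= 1) & ~np.isnan(off_dos)
        prev = out.copy()
        out = np.where(ok & np.isnan(out), t, out)
        # ambiguous: two distinct feasible values -> reset to NaN
        clash = ok & ~np.isnan(prev) & (prev != t)
        out[clash] = np.nan
    return out


def mendelian_conflict_rate(sire_dos, dam_dos, off_dos) -> float:
    """Fraction of typed markers where the offspring dosage is impossible
    given both parental dosages."""
    typed = ~np.isnan(off_dos)
    if not typed.any():
        return 0.0
    smin, smax = np.floor(sire_dos / 2), np.ceil(sire_dos / 2)
    dmin, dmax = np.floor(dam_dos / 2), np.ceil(dam_dos / 2)
    lo = smin + dmin
    hi = smax + dmax
    bad = typed & ((off_dos < lo) | (off_dos > hi))
    return float(bad.sum() / typed.sum())


def phase_parent(parent_dos: np.ndarray, mate_dos: np.ndarray,
                 offspring_dos: np.ndarray, gmap: GeneticMap,
                 max_conflict: float = 0.05) -> ParentalHaplotypes:
    """Phase one high-density parent against its full-sib offspring.

    Heterozygous markers are chained per chromosome: for each adjacent pair
    of het markers the offspring whose transmitted alleles are determined at
    both vote coupling vs repulsion; the majority (fewest recombinations)
    sets the relative phase.  An ambiguous link starts a new phase block
    (the decoder tolerates the arbitrary block orientation as one apparent
    crossover).  Het markers with no informative offspring stay unphased.
    """
    p = parent_dos.size
    for k in range(offspring_dos.shape[0]):
        rate = mendelian_conflict_rate(parent_dos, mate_dos, offspring_dos[k])
        if rate > max_conflict:
            raise MendelianError(
                f"offspring {k} conflicts with parents at {rate:.1%} of markers")
    trans = _transmitted_alleles(parent_dos, mate_dos, offspring_dos)
    het = parent_dos == 1
    prob = np.empty((p, 2))
    prob[:, 0] = parent_dos / 2.0
    prob[:, 1] = parent_dos / 2.0
    prob[het] = 0.5
    phased = ~het  # homozygous markers are trivially "phased"

    for _, idx, _pos in gmap.chrom_slices():
        het_idx = idx[het[idx]]
        if het_idx.size == 0:
            continue
        orient = np.zeros(het_idx.size, dtype=int)  # 0/1 hap label of allele-1
        informative = np.zeros(het_idx.size, dtype=bool)
        informative[0] = not np.all(np.isnan(trans[:, het_idx[0]]))
        lookback = 8  # previous het markers consulted for the phase vote
        for a in range(1, het_idx.size):
            t2 = trans[:, het_idx[a]]
            same = diff = 0
            # vote against recent informative markers; nearby het markers
            # rarely recombine, so pooled votes stay reliable
            for b in range(a - 1, max(a - 1 - lookback, -1), -1):
                if not informative[b]:
                    continue
                t1 = trans[:, het_idx[b]]
                both = ~np.isnan(t1) & ~np.isnan(t2)
                agree = int(np.sum(t1[both] == t2[both]))
                disagree = int(np.sum(t1[both] != t2[both]))
                if orient[b] == orient[a - 1]:
                    same += agree
                    diff += disagree
                else:  # earlier marker phased opposite: swap vote meaning
                    same += disagree
                    diff += agree
                if same + diff >= 6:
                    break
            if same > diff:
                orient[a] = orient[a - 1]
                informative[a] = True
            elif diff > same:
                orient[a] = 1 - orient[a - 1]
                informative[a] = True
            else:  # no informative meiosis: new block, arbitrary orientation
                orient[a] = orient[a - 1]
                informative[a] = not np.all(np.isnan(t2))
        for a, m in enumerate(het_idx):
            if informative[a]:
                prob[m, orient[a]] = 1.0
                prob[m, 1 - orient[a]] = 0.0
                phased[m] = True
    return ParentalHaplotypes(prob, phased, parent_dos.astype(float))


@dataclass
class ImputedGenotypes:
    """Expected dosages in [0, 2] with per-SNP posteriors and hard calls."""

    dosage: np.ndarray  # (k, p) posterior expected dosage; typed pass through
    hard_call: np.ndarray  # rounded expectation
    posterior: np.ndarray | None = None  # (k, p, 4) origin posteriors
    flagged: np.ndarray | None = None  # offspring with excess conflicts


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _emission(obs, ps, pm, eps):
    """P(observed dosage | state) for the 4 states (sp, dp) at one marker.

    ``ps``/``pm`` are the 2-vectors of P(allele 1) for the two haplotypes of
    sire and dam.  Mismatches get probability eps/2 each.
    """
    e = np.empty(4)
    for s in range(2):
        for d in range(2):
            prob = 0.0
            for a_s, w_s in ((1.0, ps[s]), (0.0, 1.0 - ps[s])):
                if w_s == 0.0:
                    continue
                for a_d, w_d in ((1.0, pm[d]), (0.0, 1.0 - pm[d])):
                    if w_d == 0.0:
                        continue
                    match = (a_s + a_d) == obs
                    prob += w_s * w_d * ((1.0 - eps) if match else eps / 2.0)
            e[2 * s + d] = prob
    return e


def impute_offspring(off_dos: np.ndarray, sire: ParentalHaplotypes,
                     dam: ParentalHaplotypes, gmap: GeneticMap,
                     eps: float = DEFAULT_ERROR_RATE,
                     max_conflict: float = 0.05) -> ImputedGenotypes:
    """Forward-backward decoding of haplotype origins for one offspring.

    Returns posterior expected dosages (typed markers pass through), hard
    calls (rounded expectations) and the 4-state posteriors.  An offspring
    whose typed markers conflict with the parents at more than
    ``max_conflict`` is still imputed, with emissions down-weighted by an
    inflated error rate, and is flagged.
    """
    p = off_dos.size
    conflict = mendelian_conflict_rate(sire.dosage, dam.dosage, off_dos)
    flagged = conflict > max_conflict
    eps_use = min(0.25, eps * 10) if flagged else eps

    post = np.full((p, 4), 0.25)
    expected = np.empty(p)
    for _, idx, pos in gmap.chrom_slices():
        m = idx.size
        # transitions: independent switch per parent with Haldane r
        r = _haldane_r(np.diff(pos))
        alpha = np.empty((m, 4))
        scale = np.empty(m)
        prev = np.full(4, 0.25)
        emis = np.empty((m, 4))
        for t in range(m):
            g = idx[t]
            obs = off_dos[g]
            if np.isnan(obs):
                emis[t] = 1.0
            else:
                emis[t] = _emission(obs, sire.p_allele1[g], dam.p_allele1[g],
                                    eps_use)
            if t > 0:
                rs = rd = r[t - 1]
                # switch/stay per parent; state index 2*s + d
                T_s = np.array([[1 - rs, rs], [rs, 1 - rs]])
                T_d = np.array([[1 - rd, rd], [rd, 1 - rd]])
                prev4 = alpha[t - 1].reshape(2, 2)
                prev = (T_s.T @ prev4 @ T_d).reshape(4)
            a = prev * emis[t]
            s = a.sum()
            if s <= 0:
                a = np.full(4, 0.25)
                s = 1.0
            alpha[t] = a / s
            scale[t] = s
            prev = alpha[t]
        beta_v = np.ones(4)
        for t in range(m - 1, -1, -1):
            g = idx[t]
            gamma = alpha[t] * beta_v
            gamma /= gamma.sum()
            post[g] = gamma
            if t > 0:
                rs = r[t - 1]
                T_s = np.array([[1 - rs, rs], [rs, 1 - rs]])
                T_d = T_s
                nb = (emis[t] * beta_v).reshape(2, 2)
                beta_v = (T_s @ nb @ T_d.T).reshape(4)
                bs = beta_v.sum()
                if bs > 0:
                    beta_v /= bs

    # expected dosage from posteriors and parental allele probabilities
    ps = sire.p_allele1  # (p, 2)
    pm = dam.p_allele1
    g_s = post[:, [2, 3]].sum(axis=1)  # P(sire hap = 1)
    g_d = post[:, [1, 3]].sum(axis=1)  # P(dam hap = 1)
    e_s = (1 - g_s) * ps[:, 0] + g_s * ps[:, 1]
    e_d = (1 - g_d) * pm[:, 0] + g_d * pm[:, 1]
    expected = e_s + e_d
    typed = ~np.isnan(off_dos)
    expected[typed] = off_dos[typed]
    hard = np.clip(np.round(expected), 0, 2)
    return ImputedGenotypes(expected, hard, post, np.array([flagged]))


def impute_family(family_ld: GenotypeMatrix, sire_dos: np.ndarray,
                  dam_dos: np.ndarray, hd_offspring: np.ndarray | None = None,
                  eps: float = DEFAULT_ERROR_RATE) -> GenotypeMatrix:
    """Impute every member of one full-sib family to high density.

    ``family_ld`` holds the low-density (mostly missing) dosages of the
    family members; ``hd_offspring`` optionally supplies high-density
    offspring rows used only to phase the parents (mirroring the few
    array-typed offspring of a real campaign).  Phasing falls back to the
    low-density offspring themselves when no high-density sibs are given.
    """
    gmap = family_ld.map
    phase_src = hd_offspring if hd_offspring is not None else family_ld.dosages
    sire_h = phase_parent(sire_dos, dam_dos, phase_src, gmap)
    dam_h = phase_parent(dam_dos, sire_dos, phase_src, gmap)
    out = np.empty_like(family_ld.dosages)
    for k in range(len(family_ld.ids)):
        res = impute_offspring(family_ld.dosages[k], sire_h, dam_h, gmap, eps)
        out[k] = res.dosage
    return GenotypeMatrix(family_ld.ids, gmap, out)


def _mode_fill(dos, row, parents_of, col_mode, col_mean, iid):
    """Marginal fill for one individual: population mode restricted to the
    parents' feasible transmission range, expected dosage as fallback."""
    i = row[iid]
    for m in np.where(np.isnan(dos[i]))[0]:
        s, d = parents_of(iid)
        lo, hi = 0.0, 0.0
        for parent in (s, d):
            if parent in row and not np.isnan(dos[row[parent], m]):
                pdos = dos[row[parent], m]
                lo += np.floor(pdos / 2)
                hi += np.ceil(pdos / 2)
            else:
                hi += 1.0
        if not np.isnan(col_mode[m]) and lo <= col_mode[m] <= hi:
            dos[i, m] = col_mode[m]
        elif not np.isnan(col_mean[m]):
            dos[i, m] = np.clip(np.round(col_mean[m]), lo, hi)
        else:
            dos[i, m] = lo


def fill_sporadic_missing(geno: GenotypeMatrix, fped, _gmap=None) -> GenotypeMatrix:
    """Fill sporadically missing entries in high-density data.

    Individuals whose parents are both genotyped are refilled through the
    family HMM: parents are phased against the (mostly complete) full-sib
    offspring and each missing entry gets the posterior hard call, so the
    flanking markers pin the fill even where both parents are heterozygous.
    Parents/founders themselves — and families too small to phase — fall
    back to the marginal rule: the population modal dosage restricted to the
    parents' feasible transmission range, then the expected dosage under the
    observed allele frequency.
    """
    dos = geno.dosages.copy()
    n, p = dos.shape
    ped = fped.pedigree if hasattr(fped, "pedigree") else fped
    row = geno._row

    col_mode = np.full(p, np.nan)
    col_mean = np.full(p, np.nan)
    for m in range(p):
        obs = dos[~np.isnan(dos[:, m]), m]
        if obs.size:
            vals, counts = np.unique(obs, return_counts=True)
            col_mode[m] = vals[np.argmax(counts)]
            col_mean[m] = obs.mean()

    def parents_of(iid):
        return ped.parents(iid) if iid in ped else (0, 0)

    # group offspring into full-sib families with both parents genotyped
    families: dict = {}
    singles = []
    for iid in geno.ids:
        s, d = parents_of(iid)
        if s in row and d in row:
            families.setdefault((s, d), []).append(iid)
        else:
            singles.append(iid)

    # parents/founders first so family fills see complete parents
    for iid in singles:
        _mode_fill(dos, row, parents_of, col_mode, col_mean, iid)

    for (s, d), members in families.items():
        member_rows = [row[i] for i in members]
        need = [i for i in members if np.isnan(dos[row[i]]).any()]
        if not need:
            continue
        off = dos[member_rows]
        # phase on observed entries only; NaNs are uninformative
        try:
            sire_h = phase_parent(dos[row[s]], dos[row[d]], off, geno.map)
            dam_h = phase_parent(dos[row[d]], dos[row[s]], off, geno.map)
        except MendelianError:
            for iid in need:
                _mode_fill(dos, row, parents_of, col_mode, col_mean, iid)
            continue
        for iid in need:
            res = impute_offspring(dos[row[iid]], sire_h, dam_h, geno.map)
            miss = np.isnan(dos[row[iid]])
            dos[row[iid], miss] = res.hard_call[miss]

    return GenotypeMatrix(geno.ids, geno.map, dos, geno.haplotypes)
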