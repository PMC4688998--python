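"""Phenotype adjustment, EM-REML variance components, and animal-model BLUP.

Raw ordinal scores (treated as continuous) are first adjusted for year and
location using only the replicated reference genotypes — the clones scored
in every environment are the only link between locations, so fixed effects
are estimated from them alone, with genotype identity as a blocking factor
and the first level of each factor constrained to zero.  Per-individual
means of adjusted records then enter the animal model

    y = mu + a + e,   a ~ N(0, A sigma_a^2),  e ~ N(0, I sigma_e^2)

fitted by EM-REML, and Henderson's mixed-model equations give the BLUP of
the additive effect a, which downstream serves as the training phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EnvironmentEffects:
    """Additive year and location effects; first level of each is 0."""

    year: dict
    location: dict


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    converged: bool = True
    n_iter: int = 0

    @property
    def h2(self) -> float:
        tot = self.sigma_a2 + self.sigma_e2
        if tot < 1e-12:
            return 0.0  # degenerate: report 0 by convention
        return self.sigma_a2 / tot


def estimate_environment_effects(ref_records: pd.DataFrame) -> EnvironmentEffects:
    """Least-squares year and location effects from reference-genotype records.

    Model: score ~ genotype + year + location (all categorical, treatment
    coding with the first sorted level of year and location set to 0).
    Solved by ordinary least squares on the reference records only.
    """
    df = ref_records
    if df.empty:
        raise ValueError("no reference records supplied")
    years = sorted(df["year"].unique())
    locs = sorted(df["location"].unique())
    genos = sorted(df["id"].unique())
    # design: intercept + genotype dummies (drop first) + year dummies (drop
    # first) + location dummies (drop first)
    cols = []
    names = []
    n = len(df)
    cols.append(np.ones(n))
    names.append("intercept")
    for g in genos[1:]:
        cols.append((df["id"] == g).to_numpy(float))
        names.append(("geno", g))
    for y in years[1:]:
        cols.append((df["year"] == y).to_numpy(float))
        names.append(("year", y))
    for lo in locs[1:]:
        cols.append((df["location"] == lo).to_numpy(float))
        names.append(("loc", lo))
    X = np.column_stack(cols)
    # every non-reference factor level must be supported by reference data
    for label, levels, key in (("year", years, "year"), ("location", locs, "location")):
        for lev in levels:
            if not (df[key] == lev).any():
                raise ValueError(f"{label} level {lev!r} has no reference records")
    beta, *_ = np.linalg.lstsq(X, df["score"].to_numpy(float), rcond=None)
    year_eff = {years[0]: 0.0}
    loc_eff = {locs[0]: 0.0}
    for name, b in zip(names, beta):
        if isinstance(name, tuple) and name[0] == "year":
            year_eff[name[1]] = float(b)
        elif isinstance(name, tuple) and name[0] == "loc":
            loc_eff[name[1]] = float(b)
    return EnvironmentEffects(year=year_eff, location=loc_eff)


def adjust_phenotypes(records: pd.DataFrame, effects: EnvironmentEffects) -> pd.DataFrame:
    """Subtract year and location effects; add per-record `adjusted` column.

    Raises if a record carries a year or location level with no estimated
    effect.  Adjusted values may leave the ordinal [1, 5] range.
    """
    out = records.copy()
    missing_y = set(out["year"]) - set(effects.year)
    missing_l = set(out["location"]) - set(effects.location)
    if missing_y or missing_l:
        raise ValueError(f"unadjustable levels: years {sorted(missing_y)}, "
                         f"locations {sorted(missing_l)}")
    out["adjusted"] = (out["score"].astype(float)
                       - out["year"].map(effects.year)
                       - out["location"].map(effects.location))
    return out


def individual_means(adjusted: pd.DataFrame, trait: str | None = None) -> pd.Series:
    """Per-individual mean of adjusted records (one trait)."""
    df = adjusted if trait is None else adjusted[adjusted["trait"] == trait]
    return df.groupby("id")["adjusted"].mean()


def reml_variance_components(y: pd.Series, A: pd.DataFrame,
                             tolerance: float = 1e-6,
                             max_iter: int = 10_000) -> VarianceComponents:
    """EM-REML for the animal model with a single fixed intercept.

    Uses the eigendecomposition of A restricted to the phenotyped
    individuals, so each EM step is O(n) after one O(n^3) factorization.
    Iterates until the relative change of both components drops below
    ``tolerance``; returns the last iterate flagged non-converged otherwise.
    """
    ids = [i for i in y.index if i in A.index]
    yv = y.loc[ids].to_numpy(float)
    n = yv.size
    if n < 2:
        raise ValueError("need at least 2 phenotyped individuals in A")
    vary = yv.var(ddof=1)
    if vary < 1e-12:
        return VarianceComponents(0.0, 0.0, converged=True, n_iter=0)
    Asub = A.loc[ids, ids].to_numpy(float)
    d, U = np.linalg.eigh(Asub)
    d = np.clip(d, 1e-10, None)
    ys = U.T @ yv
    xs = U.T @ np.ones(n)

    sa, se = 0.5 * vary, 0.5 * vary
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = sa * d + se  # rotated V is diagonal
        vi = 1.0 / v
        xvx = np.sum(xs * xs * vi)
        xvy = np.sum(xs * ys * vi)
        beta = xvy / xvx
        py = vi * (ys - xs * beta)  # P y in rotated coordinates
        # diag of rotated P = vi - (vi*xs)^2 / xvx
        diag_p = vi - (vi * xs) ** 2 / xvx
        # EM updates: s_new = s + s^2/n * (y'P K P y - tr(P K)), K = A or I
        tr_pa = np.sum(diag_p * d)
        tr_p = np.sum(diag_p)
        ypapy = np.sum(py * py * d)
        yppy = np.sum(py * py)
        sa_new = sa + (sa * sa / n) * (ypapy - tr_pa)
        se_new = se + (se * se / n) * (yppy - tr_p)
        sa_new = max(sa_new, 0.0)
        se_new = max(se_new, 1e-12 * vary)
        rel = max(abs(sa_new - sa) / max(sa, 1e-12),
                  abs(se_new - se) / max(se, 1e-12))
        sa, se = sa_new, se_new
        if rel < tolerance:
            converged = True
            break
    return VarianceComponents(float(sa), float(se), converged=converged, n_iter=it)


def animal_model_blup(y: pd.Series, A: pd.DataFrame,
                      variances: VarianceComponents) -> pd.Series:
    """BLUP of additive effects from Henderson's mixed-model equations.

    Individuals in A without a phenotype still receive a prediction through
    their relationships.  With sigma_a^2 = 0 the system is degenerate and
    all BLUPs are returned as 0.
    """
    all_ids = list(A.index)
    obs = [i for i in y.index if i in A.index]
    if variances.sigma_a2 <= 0:
        import warnings

        warnings.warn("sigma_a2 is zero; returning all-zero BLUPs")
        return pd.Series(0.0, index=all_ids)
    lam = variances.sigma_e2 / variances.sigma_a2
    Afull = A.to_numpy(float)
    Ainv = np.linalg.inv(Afull)
    n_all = len(all_ids)
    pos = {iid: k for k, iid in enumerate(all_ids)}
    Z = np.zeros((len(obs), n_all))
    for r, iid in enumerate(obs):
        Z[r, pos[iid]] = 1.0
    yv = y.loc[obs].to_numpy(float)
    X = np.ones((len(obs), 1))
    # [X'X  X'Z; Z'X  Z'Z + lam*Ainv] [b; a] = [X'y; Z'y]
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * Ainv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ yv, Z.T @ yv])
    sol = np.linalg.solve(lhs, rhs)
    return pd.Series(sol[1:], index=all_ids)


def blup_phenotypes(records: pd.DataFrame, A: pd.DataFrame, trait: str,
                    training_ids=None) -> tuple[pd.Series, VarianceComponents, EnvironmentEffects]:
    """Full two-stage training-phenotype pipeline for one trait.

    1. fixed year/location effects from reference records;
    2. adjust all records, per-individual means;
    3. EM-REML variance components on training individuals;
    4. animal-model BLUP over everyone in A.

    Returns (BLUPs restricted to training ids, variance components, effects).
    """
    df = records[records["trait"] == trait]
    eff = estimate_environment_effects(df[df["is_reference"]])
    adj = adjust_phenotypes(df[~df["is_reference"]], eff)
    means = individual_means(adj)
    if training_ids is not None:
        means = means.loc[[i for i in means.index if i in set(training_ids)]]
    vc = reml_variance_components(means, A)
    if vc.sigma_a2 <= 0:
        blup = pd.Series(0.0, index=A.index)
    else:
        blup = animal_model_blup(means, A, vc)
    keep = means.index if training_ids is None else [i for i in training_ids if i in blup.index]
    return blup.loc[keep], vc, eff
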