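"""Evaluation of genomic predictions: accuracy, selection response, summaries.

Accuracy is the Pearson correlation between predicted genomic breeding
values (GBV) and observed phenotypic scores within each application family,
with the asymptotic 95% confidence interval from Fisher's z-transformation;
Spearman rank correlation is added for traits whose score distribution is
highly skewed.  The realized selection differential contrasts the mean
phenotype of the k individuals with the most favourable GBV against the k
least favourable (two-sample t-test), and against the whole family
(one-sample t-test) for the directional variant.  Report aggregation,
relatedness-accuracy correlations, the no-intercept regression of accuracy
on sqrt(h2), and the pi-to-QTL-count conversion complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# the four traits with near-symmetric score distributions, used for the
# restricted family mean in the report
SYMMETRIC_TRAITS = ("attractiveness", "fruit_cropping", "fruit_size",
                    "percent_russet")


@dataclass
class AccuracyRecord:
    family: str
    trait: str
    n: int
    pearson_r: float | None
    ci_low: float | None
    ci_high: float | None
    ci_length: float | None
    spearman_rho: float | None = None
    reason: str | None = None


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic CI for a correlation: tanh(atanh(r) +/- z / sqrt(n - 3))."""
    z = stats.norm.ppf(0.5 + level / 2)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))


def accuracy(gbv, phenotypes, family: str = "", trait: str = "",
             skew_flag: bool = False) -> AccuracyRecord:
    """Pearson accuracy with Fisher-z CI; Spearman added when flagged."""
    g = np.asarray(gbv, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n = g.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(g) == 0 or np.std(y) == 0:
        return AccuracyRecord(family, trait, n, None, None, None, None,
                              reason="zero variance")
    r = float(stats.pearsonr(g, y).statistic)
    lo, hi = fisher_ci(r, n)
    rho = float(stats.spearmanr(g, y).statistic) if skew_flag else None
    return AccuracyRecord(family, trait, n, r, lo, hi, hi - lo, rho)


def skewness_flag(scores, threshold: float = 1.0) -> bool:
    """True when |Fisher-Pearson sample skewness| exceeds the threshold.

    A constant vector is flagged as skewed by convention (with a warning):
    all mass in one class is the extreme of the degenerate distributions
    this flag is meant to catch.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to judge skewness")
    if np.std(x) == 0:
        import warnings

        warnings.warn("constant scores: flagged as skewed by convention")
        return True
    return bool(abs(stats.skew(x, bias=False)) > threshold)


@dataclass
class SelectionDifferential:
    family: str
    trait: str
    k: int
    diff_top_minus_bottom: float
    t_statistic: float
    p_value: float
    directional_diff: float
    directional_p: float


def selection_differential(gbv, phenotypes, k: int = 50,
                           direction: str = "high", family: str = "",
                           trait: str = "", ids=None) -> SelectionDifferential:
    """Realized selection differential between the GBV tails.

    Individuals are ranked on GBV; the differential is the mean phenotype of
    the k most favourable minus the k least favourable, signed so that a
    positive value means selection on GBV moved the phenotype the desired
    way (``direction='low'`` for defect traits where small scores win).
    Significance: Welch two-sample t-test.  The directional differential
    compares the favourable tail to the whole family (one-sample t-test).
    Ties at rank k are broken by stable id order.
    """
    g = np.asarray(gbv, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n = g.size
    if 2 * k > n:
        raise ValueError("two-tail differential needs 2k <= n")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    order = np.argsort(g, kind="stable")  # ascending; stable over input order
    bottom, top = order[:k], order[-k:]
    if direction == "high":
        fav, unfav = top, bottom
    else:
        fav, unfav = bottom, top
    sign = 1.0 if direction == "high" else -1.0  # positive = favourable
    diff = sign * float(y[fav].mean() - y[unfav].mean())
    tt = stats.ttest_ind(y[fav], y[unfav], equal_var=False)
    dir_diff = sign * float(y[fav].mean() - y.mean())
    td = stats.ttest_1samp(y[fav], y.mean())
    return SelectionDifferential(family, trait, k, diff,
                                 sign * float(tt.statistic), float(tt.pvalue),
                                 dir_diff, float(td.pvalue))


def aggregate_report(records: pd.DataFrame,
                     symmetric_traits=SYMMETRIC_TRAITS) -> dict:
    """Aggregate a (family x trait) accuracy grid.

    ``records`` needs columns family, trait, r, and optionally ci_length.
    Missing cells (traits not scored in a family) are simply absent rows and
    are skipped; aggregates use the available cells.  Returns per-family
    means over all traits and over the four symmetric traits, per-trait
    means over families, the global maximum, and per-family mean CI length.
    """
    df = records.dropna(subset=["r"])
    per_family = df.groupby("family")["r"].mean()
    sym = df[df["trait"].isin(symmetric_traits)]
    per_family_sym = sym.groupby("family")["r"].mean()
    per_trait = df.groupby("trait")["r"].mean()
    out = {
        "mean_all_traits": per_family,
        "mean_symmetric_traits": per_family_sym,
        "trait_means": per_trait,
        "max_accuracy": float(df["r"].max()),
        "n_cells": {fam: int(c) for fam, c in df.groupby("family")["r"].count().items()},
    }
    if "ci_length" in df.columns:
        out["mean_ci_length"] = df.groupby("family")["ci_length"].mean()
    return out


def relatedness_accuracy_correlation(relatedness: pd.DataFrame,
                                     accuracies: pd.DataFrame) -> pd.DataFrame:
    """Across-family correlation of relatedness measures with accuracy.

    ``relatedness``: families x measures (e.g. top10 / top5% / top25% /
    pedigree).  ``accuracies``: families x traits.  Returns traits x
    measures of Pearson correlations computed over the shared families.
    """
    fams = [f for f in relatedness.index if f in accuracies.index]
    if len(fams) < 3:
        raise ValueError("need at least 3 families")
    out = pd.DataFrame(index=accuracies.columns, columns=relatedness.columns,
                       dtype=float)
    for trait in accuracies.columns:
        acc = accuracies.loc[fams, trait].astype(float)
        for meas in relatedness.columns:
            rel = relatedness.loc[fams, meas].astype(float)
            ok = acc.notna() & rel.notna()
            if ok.sum() < 3 or acc[ok].std() == 0 or rel[ok].std() == 0:
                out.loc[trait, meas] = np.nan
            else:
                out.loc[trait, meas] = float(np.corrcoef(rel[ok], acc[ok])[0, 1])
    return out


def accuracy_h2_regression(mean_accuracy, h2) -> float:
    """No-intercept least-squares slope of accuracy on sqrt(h2)."""
    a = np.asarray(mean_accuracy, dtype=float)
    h = np.asarray(h2, dtype=float)
    if np.all(h == 0):
        raise ValueError("all heritabilities are zero")
    x = np.sqrt(h)
    return float(np.sum(x * a) / np.sum(x * x))


def pi_to_nqtl(pi_hat: float, p: int) -> int:
    """Implied QTL count: round(pi_hat * p)."""
    if not (0.0 <= pi_hat <= 1.0):
        raise ValueError("pi_hat must be in [0, 1]")
    if p <= 0:
        raise ValueError("p must be positive")
    return int(round(pi_hat * p))


def appendix_accuracy_decomposition(gbv, tbv, h2: float,
                                    rng: np.random.Generator | None = None) -> dict:
    """Check that cor(ghat, y) ~ cor(ghat, TBV) * sqrt(h2).

    Builds y = TBV + independent residual scaled so var(TBV)/var(y) = h2 and
    returns both sides of the identity and their difference.  With
    phenotypes that are noisy readouts of the true breeding value, accuracy
    measured against phenotype is attenuated by exactly sqrt(h2).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    g = np.asarray(gbv, dtype=float)
    t = np.asarray(tbv, dtype=float)
    vt = t.var()
    if vt <= 0 or not (0 < h2 <= 1):
        raise ValueError("degenerate TBV variance or h2 outside (0, 1]")
    sigma_e = np.sqrt(vt * (1 - h2) / h2)
    y = t + rng.normal(0.0, sigma_e, size=t.size)
    cor_gy = float(np.corrcoef(g, y)[0, 1])
    cor_gt = float(np.corrcoef(g, t)[0, 1])
    expected = cor_gt * np.sqrt(h2)
    return {"cor_gbv_pheno": cor_gy, "cor_gbv_tbv_scaled": expected,
            "difference": cor_gy - expected}
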