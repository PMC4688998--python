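"""BayesC-pi whole-genome regression by Gibbs sampling.

The model for training phenotypes y (n individuals, p SNPs, centered
dosages W) is

    y = 1 mu + W beta + e,  e ~ N(0, I sigma_e^2)

with a point-mass mixture prior on each SNP effect: beta_m = 0 with
probability 1 - pi and beta_m ~ N(0, sigma_beta^2) with probability pi.
The inclusion proportion pi has a Beta(1,1) prior and is sampled, so it can
be read as the proportion of SNPs that truly affect the trait.  Variances
get scaled-inverse-chi-square priors.  Per sweep the sampler updates each
indicator/effect pair from its full conditional, then mu, sigma_beta^2,
sigma_e^2 and pi.  Reported SNP effects are Rao-Blackwellized posterior
means of delta*beta, so the excluded state shrinks them toward zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit


@dataclass
class ChainConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 1
    # prior degrees of freedom for both scaled-inv-chi2 priors, and the
    # heritability split used to set their scales from var(y)
    nu: float = 4.2
    h2_prior: float = 0.5
    pi_fixed: float | None = None  # e.g. 1.0 disables pi sampling (SNP-BLUP)

    def validate(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.pi_fixed is not None and not (0 < self.pi_fixed <= 1):
            raise ValueError("pi_fixed must be in (0, 1]")


@dataclass
class DesignMatrix:
    """Centered dosage design; application rows reuse the training means."""

    W: pd.DataFrame
    training_means: pd.Series
    excluded: list = field(default_factory=list)

    @classmethod
    def from_dosages(cls, X: pd.DataFrame, training_ids=None) -> "DesignMatrix":
        trn = X if training_ids is None else X.loc[list(training_ids)]
        if np.isnan(X.to_numpy(dtype=float)).any():
            raise ValueError("NaN in dosage matrix; impute before building the design")
        means = trn.mean(axis=0)
        var = trn.var(axis=0, ddof=0)
        keep = var > 0
        excluded = list(X.columns[~keep])
        W = X.loc[:, keep] - means[keep]
        return cls(W, means[keep], excluded)

    def center_new(self, X_app: pd.DataFrame) -> pd.DataFrame:
        missing = [s for s in self.W.columns if s not in X_app.columns]
        if missing:
            raise ValueError(f"application genotypes miss {len(missing)} model "
                             f"SNPs, e.g. {missing[:5]}")
        return X_app[self.W.columns] - self.training_means


@dataclass
class PredictionModel:
    snp_effects: pd.Series  # posterior mean of delta*beta per SNP
    inclusion_prob: pd.Series
    pi_hat: float
    sigma_beta2: float
    sigma_e2: float
    intercept: float
    training_means: pd.Series
    chain: ChainConfig
    effect_sd: pd.Series | None = None  # posterior sd of delta*beta

    def to_json(self, path) -> None:
        payload = {
            "pi_hat": self.pi_hat,
            "sigma_beta2": self.sigma_beta2,
            "sigma_e2": self.sigma_e2,
            "intercept": self.intercept,
            "chain": {
                "iterations": self.chain.iterations,
                "burn_in": self.chain.burn_in,
                "thinning": self.chain.thinning,
                "seed": self.chain.seed,
            },
            "snps": self.snp_effects.index.tolist(),
            "effects": self.snp_effects.tolist(),
            "inclusion_prob": self.inclusion_prob.tolist(),
            "training_means": self.training_means.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@njit(cache=True)
def _gibbs(W, y, n_iter, burn_in, thin, nu, s_beta, s_e, pi_init, sample_pi,
           seed):  # pragma: no cover - exercised via fit_bayescpi
    np.random.seed(seed)
    n, p = W.shape
    wtw = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += W[i, j] * W[i, j]
        wtw[j] = acc

    beta = np.zeros(p)
    delta = np.zeros(p, dtype=np.int64)
    mu = y.mean()
    r = y - mu  # residual  y - mu - W beta
    sigma_b2 = s_beta
    sigma_e2 = s_e
    pi = pi_init

    n_save = (n_iter - burn_in) // thin
    sum_effect = np.zeros(p)
    sum_effect2 = np.zeros(p)
    sum_incl = np.zeros(p)
    sum_pi = 0.0
    sum_sb2 = 0.0
    sum_se2 = 0.0
    sum_mu = 0.0
    saved = 0

    for it in range(n_iter):
        log_pi_ratio = np.log(pi) - np.log(1.0 - pi) if pi < 1.0 else 1e30
        n_incl = 0
        for j in range(p):
            if wtw[j] <= 0.0:
                continue
            # remove SNP j from the residual
            bj = beta[j]
            rhs = 0.0
            if bj != 0.0:
                for i in range(n):
                    r[i] += W[i, j] * bj
            for i in range(n):
                rhs += W[i, j] * r[i]
            c = wtw[j]
            v1 = c * sigma_b2 + sigma_e2
            # log Bayes factor for inclusion
            logbf = 0.5 * (rhs * rhs * sigma_b2 / (sigma_e2 * v1)
                           - np.log(v1 / sigma_e2))
            if pi >= 1.0:
                include = True
            else:
                u = np.random.random()
                # p(delta=1) = 1 / (1 + exp(-(logbf + log_pi_ratio)))
                z = logbf + log_pi_ratio
                if z > 35.0:
                    include = True
                elif z < -35.0:
                    include = False
                else:
                    include = u < 1.0 / (1.0 + np.exp(-z))
            if include:
                lam = sigma_e2 / sigma_b2
                mean = rhs / (c + lam)
                sd = np.sqrt(sigma_e2 / (c + lam))
                bj_new = mean + sd * np.random.standard_normal()
                beta[j] = bj_new
                delta[j] = 1
                n_incl += 1
                for i in range(n):
                    r[i] -= W[i, j] * bj_new
            else:
                beta[j] = 0.0
                delta[j] = 0

        # intercept (flat prior)
        rmean = 0.0
        for i in range(n):
            r[i] += mu
        for i in range(n):
            rmean += r[i]
        rmean /= n
        mu = rmean + np.sqrt(sigma_e2 / n) * np.random.standard_normal()
        for i in range(n):
            r[i] -= mu

        # common effect variance: scaled-inv-chi2(nu + m, ...)
        ssb = 0.0
        for j in range(p):
            if delta[j] == 1:
                ssb += beta[j] * beta[j]
        df_b = nu + n_incl
        chi2 = 2.0 * np.random.standard_gamma(0.5 * df_b)
        sigma_b2 = (ssb + nu * s_beta) / chi2

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        df_e = nu + n
        chi2 = 2.0 * np.random.standard_gamma(0.5 * df_e)
        sigma_e2 = (sse + nu * s_e) / chi2

        if sample_pi:
            a = 1.0 + n_incl
            b = 1.0 + p - n_incl
            ga = np.random.standard_gamma(a)
            gb = np.random.standard_gamma(b)
            pi = ga / (ga + gb)
            if pi < 1e-6:
                pi = 1e-6
            if pi > 1.0 - 1e-6:
                pi = 1.0 - 1e-6

        if it >= burn_in and (it - burn_in) % thin == 0:
            saved += 1
            for j in range(p):
                val = beta[j] if delta[j] == 1 else 0.0
                sum_effect[j] += val
                sum_effect2[j] += val * val
                sum_incl[j] += delta[j]
            sum_pi += pi
            sum_sb2 += sigma_b2
            sum_se2 += sigma_e2
            sum_mu += mu

    return (sum_effect / saved,
            np.sqrt(np.maximum(sum_effect2 / saved - (sum_effect / saved) ** 2, 0.0)),
            sum_incl / saved, sum_pi / saved, sum_sb2 / saved,
            sum_se2 / saved, sum_mu / saved, saved)


def fit_bayescpi(design: DesignMatrix, y: pd.Series,
                 chain: ChainConfig | None = None) -> PredictionModel:
    """Run the Gibbs sampler and return posterior summaries.

    ``y`` must cover exactly the rows of the design (training individuals).
    Raises on constant y or NaNs in the design.
    """
    chain = ChainConfig() if chain is None else chain
    chain.validate()
    Wdf = design.W.loc[y.index]
    W = np.ascontiguousarray(Wdf.to_numpy(dtype=np.float64))
    yv = y.to_numpy(dtype=np.float64)
    if np.isnan(W).any():
        raise ValueError("NaN in design matrix")
    if np.isnan(yv).any():
        raise ValueError("NaN in phenotypes")
    vary = yv.var()
    if vary < 1e-14:
        raise ValueError("constant phenotype: nothing to fit")
    p = W.shape[1]
    # prior scales from var(y) split by h2_prior; effect-variance scale
    # spread over the expected number of included SNPs
    pi0 = chain.pi_fixed if chain.pi_fixed is not None else 0.5
    mean_css = float(np.mean((W**2).sum(axis=0) / W.shape[0]))
    s_beta = chain.h2_prior * vary / max(pi0 * p * mean_css, 1e-12)
    s_e = (1.0 - chain.h2_prior) * vary
    sample_pi = chain.pi_fixed is None
    pi_init = 0.5 if sample_pi else float(chain.pi_fixed)

    (eff, eff_sd, incl, pi_hat, sb2, se2, mu, n_saved) = _gibbs(
        W, yv, chain.iterations, chain.burn_in, chain.thinning,
        chain.nu, s_beta, s_e, pi_init, sample_pi,
        int(chain.seed) % (2**31),
    )
    snps = Wdf.columns
    return PredictionModel(
        snp_effects=pd.Series(eff, index=snps),
        inclusion_prob=pd.Series(incl, index=snps),
        pi_hat=float(pi_hat) if sample_pi else float(pi_init),
        sigma_beta2=float(sb2),
        sigma_e2=float(se2),
        intercept=float(mu),
        training_means=design.training_means,
        chain=chain,
        effect_sd=pd.Series(eff_sd, index=snps),
    )


def predict_gbv(model: PredictionModel, X_app: pd.DataFrame,
                trait: str = "trait1") -> pd.DataFrame:
    """Genomic breeding values: g_i = sum_m w_im * effect_m (no intercept).

    ``X_app`` holds raw (possibly fractional, imputed) dosages; centering
    uses the training means stored in the model.
    """
    missing = [s for s in model.snp_effects.index if s not in X_app.columns]
    if missing:
        raise ValueError(f"application genotypes missing model SNPs: {missing[:5]} "
                         f"({len(missing)} total)")
    Wapp = X_app[model.snp_effects.index] - model.training_means
    gbv = Wapp.to_numpy(dtype=float) @ model.snp_effects.to_numpy()
    return pd.DataFrame({"id": X_app.index, "trait": trait, "gbv": gbv})


def relative_effects(model: PredictionModel, y_train: pd.Series) -> dict:
    """|effect| / sd(y_train) per SNP, with the summaries used for reporting:
    the maximum and the fraction of effects below 1e-4."""
    sd = float(np.std(y_train.to_numpy(dtype=float), ddof=1))
    if sd <= 0:
        raise ValueError("zero phenotypic standard deviation")
    rel = model.snp_effects.abs() / sd
    return {
        "relative_effects": rel,
        "max": float(rel.max()),
        "fraction_below_1e4": float((rel < 1e-4).mean()),
    }


def genotyped_fraction(model: PredictionModel, genotyped_snps,
                       inclusion_threshold: float = 0.5):
    """Among SNPs with inclusion probability >= threshold, the fraction that
    was directly genotyped (vs imputed).  Returns None when nothing clears
    the threshold."""
    if not (0 < inclusion_threshold < 1):
        raise ValueError("inclusion_threshold must be in (0, 1)")
    included = model.inclusion_prob[model.inclusion_prob >= inclusion_threshold]
    if included.empty:
        return None
    geno = set(genotyped_snps)
    return float(np.mean([s in geno for s in included.index]))
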