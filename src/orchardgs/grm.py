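"""Training-standardized genomic relationship matrix and relatedness summaries.

Dosages are standardized per SNP with the mean and (divide-by-N) standard
deviation computed in the training population only; the genomic relationship
matrix is then G = W'W / p.  Training-based standardization gives two exact
identities: the mean relatedness of any individual to the whole training set
is 0, and the mean training diagonal is 1.  Top-N relatedness (mean of the N
largest relationships of a candidate to the training set) summarizes how
well the training population covers each selection candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StandardizedDosages:
    W: pd.DataFrame  # individuals x retained SNPs
    means: pd.Series  # per-SNP training mean
    sds: pd.Series  # per-SNP training sd (divide-by-N)
    excluded: list  # SNPs monomorphic in training


def standardize(X: pd.DataFrame, training_ids) -> StandardizedDosages:
    """Standardize dosage columns by training mean and divide-by-N sd.

    SNPs with zero variance in the training rows are excluded (and listed).
    """
    trn = X.loc[list(training_ids)]
    means = trn.mean(axis=0)
    sds = trn.std(axis=0, ddof=0)
    keep = sds > 0
    excluded = list(X.columns[~keep])
    if not keep.any():
        raise ValueError("all SNPs are monomorphic in the training population")
    W = (X.loc[:, keep] - means[keep]) / sds[keep]
    return StandardizedDosages(W, means[keep], sds[keep], excluded)


def compute_g(W: pd.DataFrame, p: int | None = None) -> pd.DataFrame:
    """G = W W' / p over individuals (rows of W)."""
    p = W.shape[1] if p is None else p
    if p == 0:
        raise ValueError("no SNPs retained (p = 0)")
    G = W.to_numpy() @ W.to_numpy().T / p
    return pd.DataFrame(G, index=W.index, columns=W.index)


def resolve_top_k(spec, n_training: int) -> int:
    """A count, or a fraction rounded to the nearest integer (minimum 1)."""
    if isinstance(spec, float) and 0 < spec < 1:
        k = max(1, int(round(spec * n_training)))
    else:
        k = int(spec)
    if not (1 <= k <= n_training):
        raise ValueError(f"top-k spec {spec!r} outside 1..{n_training}")
    return k


def top_n_relatedness(G: pd.DataFrame, individual, training_ids, spec) -> float:
    """Mean of the k largest relationships of one individual to training."""
    trn = [i for i in training_ids if i != individual]
    if not trn:
        raise ValueError("training set is empty")
    k = resolve_top_k(spec, len(trn))
    vals = np.sort(G.loc[individual, trn].to_numpy())[::-1]
    return float(vals[:k].mean())


def family_relatedness_summary(G: pd.DataFrame, families: dict, training_ids,
                               specs=(10, 0.05, 0.25)) -> pd.DataFrame:
    """Within-family mean and sd of individual top-N relatedness.

    ``families`` maps family name -> list of member ids.  Returns a long
    table (family, measure, mean, sd, n); sd uses N-1 and is null for
    families of size 1.
    """
    rows = []
    for spec in specs:
        label = f"top{spec}" if not (isinstance(spec, float) and spec < 1) \
            else f"top{spec * 100:g}%"
        for fam, members in families.items():
            if not members:
                raise ValueError(f"family {fam!r} is empty")
            vals = np.array([top_n_relatedness(G, i, training_ids, spec)
                             for i in members])
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            rows.append((fam, label, float(vals.mean()), sd, vals.size))
    return pd.DataFrame(rows, columns=["family", "measure", "mean", "sd", "n"])


def ld_decay(W: pd.DataFrame, gmap, bins=((0, 1), (1, 5), (5, 20))) -> pd.DataFrame:
    """Mean squared dosage correlation (r^2) per map-distance bin.

    Pairs are within-chromosome only.  Also reports the adjacent-pair mean
    under the label ``adjacent``.  Bins with no pairs get a null mean.
    """
    frame = gmap.frame.set_index("snp")
    cols = [c for c in W.columns if c in frame.index]
    sub = W[cols].to_numpy()
    chroms = frame.loc[cols, "chrom"].to_numpy()
    pos = frame.loc[cols, "pos_cM"].to_numpy()
    std = sub.std(axis=0, ddof=0)
    ok = std > 0
    C = np.corrcoef(sub[:, ok].T)
    r2 = C**2
    chroms, pos = chroms[ok], pos[ok]
    rows = []
    adj_vals = []
    bin_vals = {b: [] for b in bins}
    for c in np.unique(chroms):
        sel = np.where(chroms == c)[0]
        if sel.size < 2:
            continue
        order = sel[np.argsort(pos[sel])]
        pc = pos[order]
        for a in range(order.size):
            adj = None
            for b in range(a + 1, order.size):
                d = pc[b] - pc[a]
                if adj is None:
                    adj_vals.append(r2[order[a], order[b]])
                    adj = d
                for lo, hi in bins:
                    if lo <= d < hi:
                        bin_vals[(lo, hi)].append(r2[order[a], order[b]])
    for (lo, hi), vals in bin_vals.items():
        rows.append((f"{lo}-{hi}", float(np.mean(vals)) if vals else np.nan, len(vals)))
    rows.append(("adjacent", float(np.mean(adj_vals)) if adj_vals else np.nan,
                 len(adj_vals)))
    return pd.DataFrame(rows, columns=["bin", "mean_r2", "n_pairs"])


def write_grm(G: pd.DataFrame, path) -> None:
    G.to_csv(path, sep="\t", index_label="id")
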