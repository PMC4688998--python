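"""Pedigree handling and the additive (numerator) relationship matrix.

A pedigree is a list of (id, sire, dam) records with ``0`` (or ``None``)
marking an unknown parent.  The additive relationship matrix A holds the
pedigree-expected additive relationships: a_ij = 2 * kinship(i, j), with
diagonal 1 + F_i where F_i is the inbreeding coefficient.  A is built with
the tabular (recursive) method, which is O(n^2) and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass
class Pedigree:
    """Ordered pedigree records; parents precede offspring after sorting.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, topologically ordered once validated.
    sire, dam : dict
        id -> parent id, with :data:`UNKNOWN` (``0``) for unknown parents.
    """

    ids: list = field(default_factory=list)
    sire: dict = field(default_factory=dict)
    dam: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (id, sire, dam) tuples."""
        ped = cls()
        for iid, s, d in records:
            ped.add(iid, s, d)
        return ped

    def add(self, iid, sire=UNKNOWN, dam=UNKNOWN) -> None:
        if iid in self.sire:
            raise PedigreeError(f"duplicated id {iid!r}")
        self.ids.append(iid)
        self.sire[iid] = UNKNOWN if sire in (None, UNKNOWN, "0") else sire
        self.dam[iid] = UNKNOWN if dam in (None, UNKNOWN, "0") else dam

    def parents(self, iid):
        return self.sire[iid], self.dam[iid]

    def is_founder(self, iid) -> bool:
        return self.sire[iid] == UNKNOWN and self.dam[iid] == UNKNOWN

    @property
    def founders(self):
        return [i for i in self.ids if self.is_founder(i)]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, iid) -> bool:
        return iid in self.sire

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.sire[i] for i in self.ids],
                "dam": [self.dam[i] for i in self.ids],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls.from_records(df[["id", "sire", "dam"]].itertuples(index=False))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str).fillna("0")
        return cls.from_frame(df)


def sort_and_validate(ped: Pedigree) -> Pedigree:
    """Topologically sort a pedigree so every parent precedes its offspring.

    Parents referenced but never listed are appended as founders (orphan
    parents).  A cycle (an individual that is its own ancestor) raises
    :class:`PedigreeError` naming one individual on the cycle.
    """
    order: list = []
    state: dict = {}  # 0 = on stack (visiting), 1 = done

    def visit(root):
        # iterative DFS; parents are emitted before their offspring
        stack = [root]
        while stack:
            node = stack[-1]
            if state.get(node) == 1:
                stack.pop()
                continue
            state.setdefault(node, 0)
            pending = []
            for p in ped.parents(node):
                if p == UNKNOWN or p not in ped.sire or state.get(p) == 1:
                    continue
                if p == node or state.get(p) == 0:
                    raise PedigreeError(f"cycle detected involving {node!r}")
                pending.append(p)
            if pending:
                stack.extend(pending)
            else:
                state[node] = 1
                order.append(node)
                stack.pop()

    for iid in ped.ids:
        visit(iid)

    out = Pedigree()
    # orphan parents (referenced but never listed) become founders up front
    for iid in order:
        for p in ped.parents(iid):
            if p != UNKNOWN and p not in ped.sire and p not in out.sire:
                out.add(p)
    for iid in order:
        out.add(iid, *ped.parents(iid))
    return out


def build_a_matrix(ped: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Requires a validated (topologically ordered) pedigree.  Unknown parents
    are treated as unrelated, non-inbred founders.  Returns a symmetric
    DataFrame indexed by individual id; diagonal entries equal 1 + F.
    """
    ids = ped.ids
    n = len(ids)
    idx = {iid: k for k, iid in enumerate(ids)}
    A = np.zeros((n, n))
    for i, iid in enumerate(ids):
        s, d = ped.parents(iid)
        si = idx[s] if s != UNKNOWN else -1
        di = idx[d] if d != UNKNOWN else -1
        if si >= i or di >= i:
            raise PedigreeError("pedigree not topologically ordered; run sort_and_validate")
        # relationships with all previous individuals
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0:
            A[i, :i] = 0.5 * A[si, :i]
            A[i, i] = 1.0
        elif di >= 0:
            A[i, :i] = 0.5 * A[di, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return pd.DataFrame(A, index=ids, columns=ids)


def pedigree_family_relatedness(A: pd.DataFrame, family_members, training_members) -> float:
    """Mean additive relationship between a family and the training set.

    Averages a_ij over all (family i, training j) pairs, excluding self
    pairs when the two sets overlap.
    """
    fam = list(family_members)
    trn = list(training_members)
    if not fam or not trn:
        raise ValueError("family and training sets must be non-empty")
    missing = [i for i in fam + trn if i not in A.index]
    if missing:
        raise KeyError(f"ids absent from A: {missing[:5]}")
    block = A.loc[fam, trn].to_numpy()
    mask = np.ones_like(block, dtype=bool)
    trn_pos = {t: j for j, t in enumerate(trn)}
    for i, f in enumerate(fam):
        j = trn_pos.get(f)
        if j is not None:
            mask[i, j] = False
    return float(block[mask].mean())


def write_a_matrix(A: pd.DataFrame, path) -> None:
    A.to_csv(path, sep="\t", index_label="id")


def read_a_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
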