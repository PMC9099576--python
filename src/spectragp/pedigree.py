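"""Pedigree numerator relationship matrix (tabular method)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from spectragp.errors import PedigreeCycleError


@dataclass
class AMatrix:
    ids: list
    values: np.ndarray  # dense symmetric PSD, diagonal >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def inverse(self) -> np.ndarray:
        # dense solve is fine at desk scale; A is PD for a valid pedigree
        return np.linalg.inv(self.values)


@njit(cache=True)
def _tabular_fill(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            a[i, i] = 1.0 + 0.5 * a[s, d]
        else:
            a[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = val
            a[j, i] = val
    return a


def build_a_matrix(pedigree: pd.DataFrame) -> AMatrix:
    """Wright's numerator relationship matrix by the tabular recursion.

    ``pedigree`` has columns id, sire, dam with '0' (or NaN) for unknown
    parents.  Parents appearing only in the sire/dam columns are added as
    founders.  Rows are sorted parents-before-offspring internally; a cycle
    (an individual among its own ancestors) raises
    :class:`~spectragp.errors.PedigreeCycleError`.
    """
    ped = pedigree.astype(str)
    known = {"0", "nan", "None", ""}
    parents = {}
    ids = list(dict.fromkeys(ped["id"]))
    id_set = set(ids)
    for _, row in ped.iterrows():
        s = row["sire"] if row["sire"] not in known else None
        d = row["dam"] if row["dam"] not in known else None
        parents[row["id"]] = (s, d)
        for p in (s, d):
            if p is not None and p not in id_set:
                ids.append(p)
                id_set.add(p)
                parents[p] = (None, None)

    # Kahn topological sort: parents before offspring
    order: list[str] = []
    placed: set[str] = set()
    pending = list(ids)
    while pending:
        progress = False
        remaining = []
        for i in pending:
            s, d = parents[i]
            if (s is None or s in placed) and (d is None or d in placed):
                order.append(i)
                placed.add(i)
                progress = True
            else:
                remaining.append(i)
        if not progress:
            raise PedigreeCycleError(f"pedigree cycle involving: {remaining[:5]}")
        pending = remaining

    pos = {i: k for k, i in enumerate(order)}
    sire_idx = np.array([pos[parents[i][0]] if parents[i][0] is not None else -1
                         for i in order], dtype=np.int64)
    dam_idx = np.array([pos[parents[i][1]] if parents[i][1] is not None else -1
                        for i in order], dtype=np.int64)
    a = _tabular_fill(sire_idx, dam_idx)
    # return in the original id order
    perm = np.array([pos[i] for i in ids])
    return AMatrix(ids, a[np.ix_(perm, perm)])
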