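"""Pedigree utilities: topological ordering, kinship, inbreeding and the
additive relationship matrix.

A pedigree is a DataFrame with columns ``id``, ``sire``, ``dam``; unknown
parents are 0 (or NA).  The additive relationship matrix A follows the
tabular method (Henderson): A_ii = 1 + 0.5 A_{sire,dam}, A_ij = 0.5
(A_{i,sire(j)} + A_{i,dam(j)}) with unknown parents contributing zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN = 0


def _normalise(pedigree: pd.DataFrame) -> pd.DataFrame:
    ped = pedigree[["id", "sire", "dam"]].copy()
    for col in ("sire", "dam"):
        ped[col] = ped[col].fillna(UNKNOWN)
    return ped


def topological_order(pedigree: pd.DataFrame) -> list:
    """Ids ordered so every parent precedes its offspring.

    Raises ``ValueError`` on cycles (an individual its own ancestor) or a
    parent missing from the id column.
    """
    ped = _normalise(pedigree)
    parents = {row.id: (row.sire, row.dam) for row in ped.itertuples()}
    for i, (s, d) in parents.items():
        for p in (s, d):
            if p != UNKNOWN and p not in parents:
                raise ValueError(f"parent {p!r} of {i!r} not in pedigree")
    order: list = []
    state: dict = {}

    def visit(i) -> None:
        stack = [(i, False)]
        while stack:
            node, done = stack.pop()
            if done:
                state[node] = 2
                order.append(node)
                continue
            if state.get(node) == 1:
                raise ValueError(f"pedigree cycle through {node!r}")
            if state.get(node) == 2:
                continue
            state[node] = 1
            stack.append((node, True))
            for p in parents[node]:
                if p != UNKNOWN and state.get(p) != 2:
                    if state.get(p) == 1:
                        raise ValueError(f"pedigree cycle through {p!r}")
                    stack.append((p, False))

    for i in parents:
        if state.get(i) != 2:
            visit(i)
    return order


def kinship(pedigree: pd.DataFrame) -> dict:
    """Pairwise kinship (coancestry) via the recursive definition.

    Returns a dict keyed by frozenset pairs (and singletons for self
    kinship).  Intended for moderate pedigrees; the survival models use
    :func:`additive_relationship` instead.
    """
    ped = _normalise(pedigree)
    parents = {row.id: (row.sire, row.dam) for row in ped.itertuples()}
    order = topological_order(ped)
    rank = {i: k for k, i in enumerate(order)}
    memo: dict = {}

    def phi(a, b) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        key = (a, b) if rank[a] <= rank[b] else (b, a)
        if key in memo:
            return memo[key]
        x, y = key
        if x == y:
            s, d = parents[x]
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # y is the later-born of the pair; recurse through its parents
            s, d = parents[y]
            val = 0.5 * (phi(x, s) + phi(x, d))
        memo[key] = val
        return val

    for i in order:
        phi(i, i)
    return {"phi": phi, "memo": memo}


def inbreeding_coefficients(pedigree: pd.DataFrame) -> pd.Series:
    """Pedigree inbreeding coefficient F per individual.

    F(i) is the kinship of i's parents; founders and individuals with an
    unknown parent get 0.
    """
    ped = _normalise(pedigree)
    k = kinship(ped)["phi"]
    vals = {row.id: k(row.sire, row.dam) for row in ped.itertuples()}
    return pd.Series(vals, name="f_ped")


def additive_relationship(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Additive relationship matrix A by the tabular method.

    Rows/columns are indexed by individual id in topological order of the
    input pedigree's ids (parents first).
    """
    ped = _normalise(pedigree)
    order = topological_order(ped)
    idx = {i: k for k, i in enumerate(order)}
    parents = {row.id: (row.sire, row.dam) for row in ped.itertuples()}
    n = len(order)
    A = np.zeros((n, n))
    for j, i in enumerate(order):
        s, d = parents[i]
        si = idx.get(s, -1) if s != UNKNOWN else -1
        di = idx.get(d, -1) if d != UNKNOWN else -1
        a_sd = A[si, di] if si >= 0 and di >= 0 else 0.0
        A[j, j] = 1.0 + 0.5 * a_sd
        row = np.zeros(j)
        if si >= 0:
            row += 0.5 * A[:j, si]
        if di >= 0:
            row += 0.5 * A[:j, di]
        A[j, :j] = row
        A[:j, j] = row
    return pd.DataFrame(A, index=order, columns=order)
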