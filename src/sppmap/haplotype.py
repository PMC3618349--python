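"""Consensus haplotypes per unigene, with splitting at internal recombination.

Most polymorphic unigenes give identical calls across all of their SPP
ranges within every RIL, so one consensus locus suffices.  A minority
show a consistent positional switch (A calls on one side of the
transcript, B on the other, in one or more RILs) — the signature of a
crossover inside the unigene.  Those unigenes are split at the position
minimising within-side disagreement and contribute two loci (5'- and
3'-half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .sppcall import MISSING, RangeSet

__all__ = [
    "LocusSet",
    "consensus_haplotype",
    "build_loci",
    "assign_codes",
    "code_to_index",
]


@dataclass
class LocusSet:
    """Consensus loci: one row per locus, calls over RILs."""

    table: pd.DataFrame  # locus_id, unigene_id, part, code, n_missing
    geno: np.ndarray     # (n_loci, n_rils)
    ril_ids: np.ndarray


def _side_consensus(g: np.ndarray) -> int:
    """Per-RIL consensus of the calls on one side of a candidate split."""
    a = int((g == 0).sum())
    b = int((g == 1).sum())
    if a == b:
        return MISSING
    return 0 if a > b else 1


def consensus_haplotype(range_geno: np.ndarray,
                        min_split_support: int = 2
                        ) -> Tuple[List[np.ndarray], List[str], Optional[int]]:
    """Collapse the (ranges x RILs) calls of one unigene into 1 or 2 loci.

    If every RIL's non-missing range calls agree, a single consensus
    locus is returned.  Otherwise, if at least ``min_split_support`` RILs
    show a clean positional switch (all-A then all-B or vice versa), the
    unigene is split at the cut minimising the total number of calls that
    disagree with their own side's per-RIL consensus, and two loci are
    returned.  RILs whose conflicting calls fit no positional pattern are
    set missing.

    Returns ``(call_vectors, parts, split_index)``; ``split_index`` is the
    number of ranges in the 5' locus, or None when not split.
    """
    n_ranges, n_rils = range_geno.shape
    conflict = np.zeros(n_rils, dtype=bool)
    for i in range(n_rils):
        vals = range_geno[:, i]
        vals = vals[vals != MISSING]
        if len(vals) and (vals != vals[0]).any():
            conflict[i] = True
    if not conflict.any() or n_ranges < 2:
        cons = np.array([_side_consensus(range_geno[:, i])
                         for i in range(n_rils)], dtype=np.int8)
        if conflict.any():
            cons[conflict] = MISSING
        return [cons], ["whole"], None

    # candidate split: cut c puts ranges [0, c) left, [c, n) right
    best_c, best_cost = None, None
    for c in range(1, n_ranges):
        cost = 0
        for i in np.flatnonzero(conflict):
            for g in (range_geno[:c, i], range_geno[c:, i]):
                g = g[g != MISSING]
                if len(g):
                    a = int((g == 0).sum())
                    cost += min(a, len(g) - a)
        if best_cost is None or cost < best_cost:
            best_c, best_cost = c, cost

    c = best_c
    support = 0
    for i in np.flatnonzero(conflict):
        left = range_geno[:c, i]
        right = range_geno[c:, i]
        left = left[left != MISSING]
        right = right[right != MISSING]
        if (len(left) and len(right)
                and (left == left[0]).all() and (right == right[0]).all()
                and left[0] != right[0]):
            support += 1
    if support < min_split_support:
        cons = np.array([_side_consensus(range_geno[:, i])
                         for i in range(n_rils)], dtype=np.int8)
        cons[conflict] = MISSING
        return [cons], ["whole"], None

    left_calls = np.empty(n_rils, dtype=np.int8)
    right_calls = np.empty(n_rils, dtype=np.int8)
    for i in range(n_rils):
        left_calls[i] = _side_consensus(range_geno[:c, i])
        right_calls[i] = _side_consensus(range_geno[c:, i])
    return [left_calls, right_calls], ["5'-half", "3'-half"], c


def build_loci(ranges: RangeSet, min_split_support: int = 2) -> LocusSet:
    """Build consensus loci for every unigene with at least one SPP range."""
    rows = []
    geno_rows = []
    locus_id = 0
    t = ranges.table
    for u, sub in t.groupby("unigene_id", sort=True):
        order = sub.sort_values("start").index.to_numpy()
        g = ranges.geno[t.index.get_indexer(order)]
        calls_list, parts, _ = consensus_haplotype(g, min_split_support)
        for calls, part in zip(calls_list, parts):
            rows.append({
                "locus_id": locus_id,
                "unigene_id": int(u),
                "part": part,
                "n_missing": int((calls == MISSING).sum()),
            })
            geno_rows.append(calls)
            locus_id += 1
    table = pd.DataFrame(rows, columns=["locus_id", "unigene_id", "part",
                                        "n_missing"])
    geno = (np.vstack(geno_rows) if geno_rows
            else np.empty((0, len(ranges.ril_ids)), dtype=np.int8))
    loci = LocusSet(table=table, geno=geno, ril_ids=ranges.ril_ids)
    return assign_codes(loci)


# ---------------------------------------------------------------------------
# four-letter marker codes
# ---------------------------------------------------------------------------

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _index_to_code(i: int) -> str:
    if not 0 <= i < 26 ** 4:
        raise ValueError(f"locus index {i} outside four-letter code range")
    out = []
    for _ in range(4):
        out.append(_ALPHA[i % 26])
        i //= 26
    return "".join(reversed(out))


def code_to_index(code: str) -> int:
    """Inverse of the four-letter code enumeration (AAAA -> 0)."""
    if len(code) != 4 or any(ch not in _ALPHA for ch in code):
        raise ValueError(f"invalid four-letter code {code!r}")
    i = 0
    for ch in code:
        i = i * 26 + _ALPHA.index(ch)
    return i


def assign_codes(loci: LocusSet) -> LocusSet:
    """Attach deterministic four-letter codes AAAA, AAAB, ... to loci."""
    if len(loci.table) > 26 ** 4:
        raise ValueError("more loci than four-letter codes")
    codes = [_index_to_code(i) for i in range(len(loci.table))]
    table = loci.table.copy()
    table["code"] = codes
    return LocusSet(table=table, geno=loci.geno, ril_ids=loci.ril_ids)


def conversion_table(loci: LocusSet) -> pd.DataFrame:
    """code <-> unigene_id conversion table."""
    return loci.table[["code", "locus_id", "unigene_id", "part"]].copy()
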