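"""Map curation: heterozygosity masking and double-recombinant removal.

Residual heterozygosity in an F7 RIL cannot be expressed by a biallelic
A/B caller; inside a heterozygous tract the calls oscillate between the
two parents or drop out, which the mapper misreads as tight double
crossovers and inflates genetic distances (every 1% genotyping error in
a marker adds roughly 2 cM).  Curation therefore proceeds in two
stages, each of which only ever converts calls to missing:

1. detect heterozygous regions with a sliding window of three ordered
   markers (a window showing an apparent double crossover or two or
   more missing calls is het-indicative; clustered windows form a
   region) and mask them;
2. mask remaining apparent double recombinants — single calls that
   disagree with both of their agreeing nearest non-missing flanking
   markers, where the flanks are close enough that a real double
   crossover is negligible — iterated to a fixpoint.

After each stage the marker order and genetic distances are
recalculated within the existing linkage groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .sppcall import MISSING
from .linkage import (
    GenotypeMatrix,
    LinkageGroupMap,
    LinkageMap,
    RecPairs,
    map_positions,
    order_markers,
    pairwise_r,
)

__all__ = [
    "detect_het_regions",
    "mask_het",
    "mask_double_recombinants",
    "count_double_recombinants",
    "remap",
    "curate_map",
    "CurationResult",
]

HET_WINDOW = 3


def expanded_orders(gm: GenotypeMatrix, lmap: LinkageMap):
    """Full locus order per group, with per-locus cM positions.

    Bin members are expanded at their representative's map position,
    sorted by code within a bin.  Returns ``{label: (order, positions)}``.
    """
    codes = gm.loci["code"].to_numpy()
    out = {}
    for g in lmap.groups:
        rep_members = {
            int(rep): members[np.argsort(codes[members])]
            for rep, members in zip(g.bins.representatives, g.bins.members)
        }
        order_parts = []
        pos_parts = []
        for r, p in zip(g.order, g.positions):
            mem = rep_members[int(r)]
            order_parts.append(mem)
            pos_parts.append(np.full(len(mem), p))
        out[g.label] = (np.concatenate(order_parts), np.concatenate(pos_parts))
    return out


def _het_indicative(calls: np.ndarray) -> np.ndarray:
    """Per 3-marker window: True when the window suggests heterozygosity.

    Heterozygous tracts betray themselves by apparent double crossovers
    (the middle marker differing from both flanks: A-B-A or B-A-B) or by
    dropout (two or more missing calls).  A single transition (A-A-B) is
    an ordinary crossover junction and must not be flagged, otherwise
    every real recombination event would be masked away.
    """
    n = len(calls)
    if n < HET_WINDOW:
        return np.zeros(0, dtype=bool)
    w = np.lib.stride_tricks.sliding_window_view(calls, HET_WINDOW)
    n_miss = (w == MISSING).sum(axis=1)
    complete = n_miss == 0
    double = complete & (w[:, 0] == w[:, 2]) & (w[:, 1] != w[:, 0])
    return double | (n_miss >= 2)


def detect_het_regions(gm: GenotypeMatrix, lmap: LinkageMap,
                       cluster_min: int = 2) -> pd.DataFrame:
    """Heterozygous regions per RIL along each ordered linkage group.

    Het-indicative 3-marker windows whose starts lie within two markers
    of each other are chained; chains of at least ``cluster_min``
    windows become regions.  Returns columns ``ril, group, start_index,
    end_index, n_windows, n_missing`` with marker-order indices
    (inclusive).
    """
    rows = []
    orders = expanded_orders(gm, lmap)
    for g in lmap.groups:
        order, _ = orders[g.label]
        sub = gm.geno[order]  # markers x rils
        for ri in range(gm.n_rils):
            ind = _het_indicative(sub[:, ri])
            starts = np.flatnonzero(ind)
            if len(starts) == 0:
                continue
            # chain windows that share at least one marker
            breaks = np.flatnonzero(np.diff(starts) > HET_WINDOW - 1) + 1
            for chunk in np.split(starts, breaks):
                if len(chunk) < cluster_min:
                    continue
                s, e = int(chunk[0]), int(chunk[-1] + HET_WINDOW - 1)
                seg = sub[s:e + 1, ri]
                rows.append({
                    "ril": int(gm.ril_ids[ri]),
                    "group": g.label,
                    "start_index": s,
                    "end_index": e,
                    "n_windows": int(len(chunk)),
                    "n_missing": int((seg == MISSING).sum()),
                })
    return pd.DataFrame(rows, columns=["ril", "group", "start_index",
                                       "end_index", "n_windows", "n_missing"])


def mask_het(gm: GenotypeMatrix, regions: pd.DataFrame,
             lmap: LinkageMap) -> Tuple[GenotypeMatrix, int]:
    """Set all calls inside detected het regions to missing.

    Returns the masked copy and the number of calls newly masked.
    """
    geno = gm.geno.copy()
    order_of = expanded_orders(gm, lmap)
    ril_pos = {int(r): i for i, r in enumerate(gm.ril_ids)}
    n_masked = 0
    for _, row in regions.iterrows():
        order, _ = order_of[row["group"]]
        loci = order[int(row["start_index"]):int(row["end_index"]) + 1]
        ri = ril_pos[int(row["ril"])]
        n_masked += int((geno[loci, ri] != MISSING).sum())
        geno[loci, ri] = MISSING
    return GenotypeMatrix(geno=geno, loci=gm.loci, ril_ids=gm.ril_ids), n_masked


def _singleton_mask(calls: np.ndarray,
                    positions: Optional[np.ndarray] = None,
                    max_span_cm: Optional[float] = None) -> np.ndarray:
    """True where a call disagrees with both agreeing nearest non-missing
    flanks (the apparent double-crossover signature).

    With ``positions`` and ``max_span_cm`` given, a singleton is flagged
    only when its flanking loci lie within ``max_span_cm`` of each other
    — the span where a genuine double crossover is negligible.
    """
    idx = np.flatnonzero(calls != MISSING)
    out = np.zeros(len(calls), dtype=bool)
    if len(idx) < 3:
        return out
    vals = calls[idx]
    mid = vals[1:-1]
    left = vals[:-2]
    right = vals[2:]
    bad = (left == right) & (mid != left)
    if positions is not None and max_span_cm is not None:
        span = positions[idx[2:]] - positions[idx[:-2]]
        bad &= span <= max_span_cm
    out[idx[1:-1][bad]] = True
    return out


def count_double_recombinants(gm: GenotypeMatrix, lmap: LinkageMap) -> int:
    """Number of apparent double-crossover singletons over all groups/RILs."""
    total = 0
    orders = expanded_orders(gm, lmap)
    for g in lmap.groups:
        order, _ = orders[g.label]
        sub = gm.geno[order]
        for ri in range(gm.n_rils):
            total += int(_singleton_mask(sub[:, ri]).sum())
    return total


def mask_double_recombinants(gm: GenotypeMatrix, lmap: LinkageMap,
                             max_span_cm: Optional[float] = 2.0
                             ) -> Tuple[GenotypeMatrix, int]:
    """Mask apparent double-crossover singletons, iterating to a fixpoint.

    Each pass masks every current singleton simultaneously; masking can
    expose new singletons (a flank may disappear), so passes repeat
    until nothing changes.  A singleton is masked only when its flanking
    loci lie within ``max_span_cm`` of each other: a real double
    crossover inside such a span is vanishingly improbable, whereas a
    singleton between distant flanks may be genuine recombination
    (``max_span_cm=None`` masks unconditionally).  Returns the masked
    copy and the total number of masked calls.
    """
    geno = gm.geno.copy()
    n_masked = 0
    orders = expanded_orders(gm, lmap)
    for g in lmap.groups:
        order, pos = orders[g.label]
        for ri in range(gm.n_rils):
            calls = geno[order, ri]
            while True:
                bad = _singleton_mask(calls, pos, max_span_cm)
                if not bad.any():
                    break
                calls[bad] = MISSING
                n_masked += int(bad.sum())
            geno[order, ri] = calls
    return GenotypeMatrix(geno=geno, loci=gm.loci, ril_ids=gm.ril_ids), n_masked


def remap(gm: GenotypeMatrix, lmap: LinkageMap,
          min_support: int = 30, ripple_window: int = 5
          ) -> Tuple[LinkageMap, RecPairs]:
    """Recompute marker order and distances within the existing groups.

    Group membership, bin structure and representatives are kept; only
    pairwise recombination, the order of representatives and the cM
    positions are recalculated from the (possibly masked) calls.
    """
    pairs = pairwise_r(gm, low_support_floor=min_support)
    codes = gm.loci["code"].to_numpy()
    groups = []
    for g in lmap.groups:
        order = order_markers(g.bins.representatives, pairs, codes=codes,
                              ripple_window=ripple_window)
        pos = map_positions(order, pairs, lmap.map_function,
                            lmap.ril_correction)
        groups.append(LinkageGroupMap(group_id=g.group_id, label=g.label,
                                      loci=g.loci, bins=g.bins,
                                      order=order, positions=pos))
    return (LinkageMap(groups=groups, map_function=lmap.map_function,
                       ril_correction=lmap.ril_correction), pairs)


@dataclass
class CurationResult:
    """Maps and genotype matrices at the three curation stages.

    v0 = raw map, v1 = after het masking, v2 = after double-recombinant
    masking; lengths and double-recombinant counts are recorded per
    stage.
    """

    map_v0: LinkageMap
    map_v1: LinkageMap
    map_v2: LinkageMap
    gm_v0: GenotypeMatrix
    gm_v1: GenotypeMatrix
    gm_v2: GenotypeMatrix
    het_regions: pd.DataFrame
    lengths: Tuple[float, float, float]
    double_recombinants: Tuple[int, int, int]
    n_masked_het: int
    n_masked_dr: int

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": ["v0_raw", "v1_het_masked", "v2_dr_masked"],
            "map_length_cm": self.lengths,
            "double_recombinants": self.double_recombinants,
            "n_masked": [0, self.n_masked_het, self.n_masked_dr],
        })


def curate_map(gm: GenotypeMatrix, lmap_v0: LinkageMap,
               cluster_min: int = 2, min_support: int = 30,
               ripple_window: int = 5,
               max_span_cm: Optional[float] = 2.0) -> CurationResult:
    """Run the two-stage curation from an initial map."""
    dr0 = count_double_recombinants(gm, lmap_v0)

    regions = detect_het_regions(gm, lmap_v0, cluster_min=cluster_min)
    gm1, n_het = mask_het(gm, regions, lmap_v0)
    map_v1, _ = remap(gm1, lmap_v0, min_support=min_support,
                      ripple_window=ripple_window)
    dr1 = count_double_recombinants(gm1, map_v1)

    gm2, n_dr = mask_double_recombinants(gm1, map_v1, max_span_cm=max_span_cm)
    map_v2, _ = remap(gm2, map_v1, min_support=min_support,
                      ripple_window=ripple_window)
    dr2 = count_double_recombinants(gm2, map_v2)

    return CurationResult(
        map_v0=lmap_v0, map_v1=map_v1, map_v2=map_v2,
        gm_v0=gm, gm_v1=gm1, gm_v2=gm2,
        het_regions=regions,
        lengths=(lmap_v0.total_length, map_v1.total_length,
                 map_v2.total_length),
        double_recombinants=(dr0, dr1, dr2),
        n_masked_het=n_het, n_masked_dr=n_dr,
    )
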