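"""Linkage analysis: marker filtering, recombination, bins, ordering, cM.

Loci are filtered for missing data and allelic distortion, clustered
into linkage groups by single-linkage over pairwise recombination
fractions, collapsed into genetic bins (zero observed recombination
among all pairs) and super-bins (zero recombination for some pairs but
not all, a consequence of missing data), and one representative per
bin — the locus with the least missing data — is ordered within each
group by a greedy-insertion + window-ripple search minimising COUNT,
the summed number of recombination events between adjacent markers.
Genetic distances come from the Kosambi (default) or Haldane map
function.

Because RILs accumulate recombinants over several rounds of selfing,
the apparent recombinant fraction R between tightly linked loci
converges to 2r/(1+2r) for gametic fraction r.  Distance assignment
therefore applies the inverse r = R/(2(1-R)) before the map function by
default (``ril_correction``); pairwise r̂ values are always reported as
the raw apparent fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sppcall import MISSING
from .haplotype import LocusSet

__all__ = [
    "GenotypeMatrix",
    "RecPairs",
    "BinStructure",
    "LinkageGroupMap",
    "LinkageMap",
    "filter_markers",
    "pairwise_r",
    "group_markers",
    "build_bins",
    "order_markers",
    "map_distance",
    "apparent_to_gametic",
    "map_positions",
    "build_linkage_map",
    "rescue_distorted",
    "count_objective",
]


@dataclass
class GenotypeMatrix:
    """Loci x RILs calls in {0=A, 1=B, -1=missing} with locus metadata."""

    geno: np.ndarray
    loci: pd.DataFrame  # locus_id, unigene_id, part, code, n_missing
    ril_ids: np.ndarray

    @classmethod
    def from_locus_set(cls, ls: LocusSet) -> "GenotypeMatrix":
        loci = ls.table.reset_index(drop=True)
        return cls(geno=ls.geno.copy(), loci=loci, ril_ids=ls.ril_ids)

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(geno=self.geno[idx],
                              loci=self.loci.iloc[idx].reset_index(drop=True),
                              ril_ids=self.ril_ids)

    @property
    def n_loci(self) -> int:
        return self.geno.shape[0]

    @property
    def n_rils(self) -> int:
        return self.geno.shape[1]

    def missing_counts(self) -> np.ndarray:
        return (self.geno == MISSING).sum(axis=1)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_markers(gm: GenotypeMatrix,
                   max_missing_rils: Optional[int] = None,
                   min_allele_ratio: float = 0.2
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition loci into (kept, excluded_skewed, excluded_missing).

    A locus is kept when its missing calls do not exceed
    ``max_missing_rils`` (default 12% of the population, i.e. 25 of 213)
    and its minor/major allele-count ratio is strictly greater than
    ``min_allele_ratio``.  Excluded indices are retained so that skewed
    loci can be rescued later.
    """
    if max_missing_rils is None:
        max_missing_rils = int(0.12 * gm.n_rils)
    miss = gm.missing_counts()
    nA = (gm.geno == 0).sum(axis=1)
    nB = (gm.geno == 1).sum(axis=1)
    minor = np.minimum(nA, nB).astype(float)
    major = np.maximum(nA, nB).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(major > 0, minor / major, 0.0)
    too_missing = miss > max_missing_rils
    skewed = (~too_missing) & (ratio <= min_allele_ratio)
    kept = ~(too_missing | skewed)
    return (np.flatnonzero(kept), np.flatnonzero(skewed),
            np.flatnonzero(too_missing))


# ---------------------------------------------------------------------------
# pairwise recombination
# ---------------------------------------------------------------------------

@dataclass
class RecPairs:
    """Symmetric pairwise recombination evidence over all loci.

    ``r_hat[i, j]`` is the apparent recombinant fraction
    n_recombinant / n_informative over RILs non-missing at both loci
    (NaN when none are co-observed).
    """

    n_informative: np.ndarray
    n_recombinant: np.ndarray
    r_hat: np.ndarray
    low_support_floor: int = 30

    def low_support(self) -> np.ndarray:
        return self.n_informative < self.low_support_floor

    def to_table(self, codes: Sequence[str]) -> pd.DataFrame:
        n = self.r_hat.shape[0]
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "locus_i": np.asarray(codes)[iu[0]],
            "locus_j": np.asarray(codes)[iu[1]],
            "n_informative": self.n_informative[iu],
            "n_recombinant": self.n_recombinant[iu],
            "r_hat": self.r_hat[iu],
        })


def pairwise_r(gm: GenotypeMatrix, low_support_floor: int = 30) -> RecPairs:
    """Recombinant fractions over pairwise-complete RILs for all locus pairs."""
    if gm.n_loci < 2:
        raise ValueError("need at least 2 loci")
    V = (gm.geno != MISSING).astype(np.float64)
    A = ((gm.geno == 0) & (V > 0)).astype(np.float64)
    B = ((gm.geno == 1) & (V > 0)).astype(np.float64)
    n_inf = V @ V.T
    n_rec = A @ B.T + B @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n_inf > 0, n_rec / n_inf, np.nan)
    np.fill_diagonal(r, 0.0)
    return RecPairs(n_informative=n_inf.astype(np.int64),
                    n_recombinant=n_rec.astype(np.int64),
                    r_hat=r, low_support_floor=low_support_floor)


# ---------------------------------------------------------------------------
# linkage grouping
# ---------------------------------------------------------------------------

def group_markers(pairs: RecPairs, r_max: float = 0.2,
                  min_support: int = 30,
                  anchors: Optional[Dict[int, str]] = None
                  ) -> Tuple[List[np.ndarray], List[str]]:
    """Single-linkage transitive closure over well-supported linked pairs.

    Edges connect loci with r̂ <= ``r_max`` and at least ``min_support``
    co-observed RILs.  Groups are returned largest first; ``anchors``
    (locus index -> chromosome label) relabel groups, otherwise labels
    are LG1, LG2, ... in size order.
    """
    import networkx as nx

    n = pairs.r_hat.shape[0]
    ok = ((pairs.r_hat <= r_max) & (pairs.n_informative >= min_support))
    np.fill_diagonal(ok, False)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(*np.nonzero(np.triu(ok))))
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    groups = [np.array(sorted(c)) for c in comps]
    labels = []
    for gi, g in enumerate(groups):
        label = f"LG{gi + 1}"
        if anchors:
            hits = [anchors[i] for i in g if i in anchors]
            if hits:
                label = pd.Series(hits).mode().iloc[0]
        labels.append(label)
    return groups, labels


# ---------------------------------------------------------------------------
# bins and super-bins
# ---------------------------------------------------------------------------

@dataclass
class BinStructure:
    """Bins / super-bins / singletons of one linkage group.

    ``assignments`` has one row per locus (index into the genotype
    matrix) with its bin id and class; ``representatives`` holds the
    locus chosen for mapping per bin (least missing data, ties broken by
    four-letter code).
    """

    assignments: pd.DataFrame  # locus, bin_id, bin_class
    representatives: np.ndarray
    members: List[np.ndarray] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        cls = self.assignments.drop_duplicates("bin_id")["bin_class"]
        return {
            "bins": int((cls == "bin").sum()),
            "super_bins": int((cls == "super-bin").sum()),
            "singletons": int((cls == "singleton").sum()),
        }


def build_bins(group: np.ndarray, pairs: RecPairs,
               gm: GenotypeMatrix) -> BinStructure:
    """Partition a linkage group into bins, super-bins and singletons.

    Co-observed locus pairs with r̂ = 0 form the edges of a zero-
    recombination graph.  A connected component of size >= 2 is a *bin*
    when every co-observed internal pair has r̂ = 0 and a *super-bin*
    when some internal pair recombines; isolated loci are singletons.
    """
    import networkx as nx

    sub_r = pairs.r_hat[np.ix_(group, group)]
    sub_inf = pairs.n_informative[np.ix_(group, group)]
    zero = (sub_inf > 0) & (sub_r == 0)
    np.fill_diagonal(zero, False)
    G = nx.Graph()
    G.add_nodes_from(range(len(group)))
    G.add_edges_from(zip(*np.nonzero(np.triu(zero))))

    miss = gm.missing_counts()
    codes = gm.loci["code"].to_numpy()
    rows = []
    reps = []
    members: List[np.ndarray] = []
    comps = sorted(nx.connected_components(G),
                   key=lambda c: min(codes[group[i]] for i in c))
    for bin_id, comp in enumerate(comps):
        loc = group[sorted(comp)]
        if len(loc) == 1:
            cls = "singleton"
        else:
            internal_r = sub_r[np.ix_(sorted(comp), sorted(comp))]
            internal_inf = sub_inf[np.ix_(sorted(comp), sorted(comp))]
            observed = internal_inf > 0
            np.fill_diagonal(observed, False)
            nonzero = observed & (internal_r > 0)
            cls = "super-bin" if nonzero.any() else "bin"
        order = np.lexsort((codes[loc], miss[loc]))
        reps.append(loc[order[0]])
        members.append(loc)
        for l in loc:
            rows.append({"locus": int(l), "bin_id": bin_id, "bin_class": cls})
    assignments = pd.DataFrame(rows, columns=["locus", "bin_id", "bin_class"])
    return BinStructure(assignments=assignments,
                        representatives=np.array(reps, dtype=int),
                        members=members)


def classify_bin_matrix(r_matrix: np.ndarray) -> str:
    """Classify a small all-linked marker set from its r̂ matrix.

    Upper-triangular (or full) matrix of pairwise recombination values;
    returns 'bin' when all pairs are zero, 'super-bin' when the zero-
    recombination graph is connected but some pair recombines, and
    'unlinked' when the zero graph is disconnected.
    """
    import networkx as nx

    M = np.asarray(r_matrix, dtype=float)
    M = np.where(np.isnan(M), np.inf, np.maximum(M, M.T))
    np.fill_diagonal(M, 0.0)
    n = M.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(*np.nonzero(np.triu(M == 0))))
    if not nx.is_connected(G):
        return "unlinked"
    off = M[np.triu_indices(n, k=1)]
    return "bin" if (off == 0).all() else "super-bin"


# ---------------------------------------------------------------------------
# marker ordering (COUNT criterion)
# ---------------------------------------------------------------------------

def count_objective(order: Sequence[int], n_rec: np.ndarray) -> int:
    """COUNT = summed recombination events between adjacent markers."""
    o = np.asarray(order)
    return int(n_rec[o[:-1], o[1:]].sum())


def _greedy_insertion(reps: np.ndarray, n_rec: np.ndarray) -> List[int]:
    remaining = list(reps)
    # seed with the pair of most complete loci? use the two loci with the
    # largest mutual recombination count to span the group end to end
    order = [remaining.pop(0)]
    while remaining:
        m = remaining.pop(0)
        best_pos, best_cost = 0, None
        for pos in range(len(order) + 1):
            cand = order[:pos] + [m] + order[pos:]
            cost = count_objective(cand, n_rec)
            if best_cost is None or cost < best_cost:
                best_pos, best_cost = pos, cost
        order.insert(best_pos, m)
    return order


def _two_opt_pass(order: List[int], n_rec: np.ndarray) -> Tuple[List[int], bool]:
    """Reverse any contiguous segment that lowers COUNT (path 2-opt)."""
    o = list(order)
    n = len(o)
    improved = False
    for i in range(n - 1):
        for j in range(i + 1, n):
            left = n_rec[o[i - 1], o[j]] - n_rec[o[i - 1], o[i]] if i > 0 else 0
            right = n_rec[o[i], o[j + 1]] - n_rec[o[j], o[j + 1]] if j < n - 1 else 0
            if left + right < 0:
                o[i:j + 1] = reversed(o[i:j + 1])
                improved = True
    return o, improved


def _or_opt_pass(order: List[int], n_rec: np.ndarray) -> Tuple[List[int], bool]:
    """Relocate single markers to a cheaper position."""
    o = list(order)
    improved = False
    i = 0
    while i < len(o):
        m = o[i]
        rest = o[:i] + o[i + 1:]
        base = count_objective(rest, n_rec)
        best_pos, best_cost = None, count_objective(o, n_rec)
        for pos in range(len(rest) + 1):
            add = 0
            if pos > 0:
                add += n_rec[rest[pos - 1], m]
            if pos < len(rest):
                add += n_rec[m, rest[pos]]
            if 0 < pos < len(rest):
                add -= n_rec[rest[pos - 1], rest[pos]]
            if base + add < best_cost:
                best_pos, best_cost = pos, base + add
        if best_pos is not None and best_pos != i:
            o = rest[:best_pos] + [m] + rest[best_pos:]
            improved = True
        i += 1
    return o, improved


def _ripple(order: List[int], n_rec: np.ndarray, window: int = 5,
            max_passes: int = 30) -> List[int]:
    """Local search to a COUNT optimum: 2-opt, or-opt and window ripple."""
    n = len(order)
    if n <= 2:
        return list(order)
    best = list(order)
    best_cost = count_objective(best, n_rec)
    for _ in range(max_passes):
        improved = False
        for move in (_two_opt_pass, _or_opt_pass):
            best, imp = move(best, n_rec)
            improved |= imp
        for start in range(0, n - 1):
            w = min(window, n - start)
            if w < 2:
                continue
            head, seg, tail = best[:start], best[start:start + w], best[start + w:]
            for perm in itertools.permutations(seg):
                cand = head + list(perm) + tail
                cost = count_objective(cand, n_rec)
                if cost < best_cost:
                    best, best_cost = cand, cost
                    improved = True
        cost = count_objective(best, n_rec)
        if cost < best_cost:
            best_cost = cost
        if not improved:
            break
    return best


def order_markers(reps: np.ndarray, pairs: RecPairs,
                  codes: Optional[Sequence[str]] = None,
                  ripple_window: int = 5) -> np.ndarray:
    """Order representatives by greedy insertion + window ripple on COUNT.

    Orientation is normalised so the end with the lexicographically
    smaller code (or the lower index) comes first.
    """
    reps = np.asarray(reps, dtype=int)
    if len(reps) < 2:
        return reps
    inf = pairs.n_informative[np.ix_(reps, reps)]
    if (inf == 0).any():
        bad = np.argwhere(np.triu(inf == 0, k=1))
        raise ValueError(
            f"representatives not mutually observed: {len(bad)} pairs, "
            f"e.g. {tuple(reps[bad[0]])}")
    # order by completeness so well-observed loci shape the backbone first
    start = list(reps[np.argsort(-inf.sum(axis=1))])
    order = _greedy_insertion(np.array(start), pairs.n_recombinant)
    order = _ripple(order, pairs.n_recombinant, window=ripple_window)
    first, last = order[0], order[-1]
    if codes is not None:
        key_first, key_last = codes[first], codes[last]
    else:
        key_first, key_last = first, last
    if key_last < key_first:
        order = order[::-1]
    return np.asarray(order, dtype=int)


# ---------------------------------------------------------------------------
# map distances
# ---------------------------------------------------------------------------

def map_distance(r, function: str = "kosambi"):
    """Convert recombination fraction(s) to cM.

    kosambi: 25 ln((1+2r)/(1-2r)); haldane: -50 ln(1-2r).  Requires
    0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    if function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown map function {function!r}")
    return float(d) if d.ndim == 0 else d


def apparent_to_gametic(R):
    """Invert the selfing fixed point R = 2r/(1+2r): r = R/(2(1-R)).

    The result is capped just below 0.5 so extreme apparent fractions
    remain mappable.
    """
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = R / (2.0 * (1.0 - R))
    r = np.minimum(r, 0.4999)
    return float(r) if r.ndim == 0 else r


def map_positions(order: np.ndarray, pairs: RecPairs,
                  map_function: str = "kosambi",
                  ril_correction: bool = True) -> np.ndarray:
    """Cumulative cM positions along an ordered list of representatives."""
    o = np.asarray(order, dtype=int)
    if len(o) == 0:
        return np.array([])
    R = pairs.r_hat[o[:-1], o[1:]]
    R = np.nan_to_num(R, nan=0.0)
    r = apparent_to_gametic(R) if ril_correction else np.minimum(R, 0.4999)
    d = map_distance(r, map_function)
    return np.concatenate(([0.0], np.cumsum(d)))


# ---------------------------------------------------------------------------
# whole-map assembly
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroupMap:
    group_id: int
    label: str
    loci: np.ndarray          # all loci of the group
    bins: BinStructure
    order: np.ndarray         # ordered representatives
    positions: np.ndarray     # cM, same length as order

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def max_gap(self) -> float:
        if len(self.positions) < 2:
            return 0.0
        return float(np.diff(self.positions).max())


@dataclass
class LinkageMap:
    groups: List[LinkageGroupMap]
    map_function: str = "kosambi"
    ril_correction: bool = True

    @property
    def total_length(self) -> float:
        return float(sum(g.length for g in self.groups))

    def to_table(self, gm: GenotypeMatrix) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            assign = g.bins.assignments.set_index("locus")
            for locus, pos in zip(g.order, g.positions):
                rows.append({
                    "group": g.label,
                    "position_cm": float(pos),
                    "code": gm.loci.loc[locus, "code"],
                    "unigene_id": int(gm.loci.loc[locus, "unigene_id"]),
                    "bin_id": int(assign.loc[locus, "bin_id"]),
                    "bin_class": assign.loc[locus, "bin_class"],
                })
        return pd.DataFrame(rows)


def build_linkage_map(gm: GenotypeMatrix,
                      pairs: Optional[RecPairs] = None,
                      groups: Optional[List[np.ndarray]] = None,
                      labels: Optional[List[str]] = None,
                      r_max: float = 0.2,
                      min_support: int = 30,
                      map_function: str = "kosambi",
                      ril_correction: bool = True,
                      min_group_size: int = 2,
                      ripple_window: int = 5) -> Tuple[LinkageMap, RecPairs]:
    """Group, bin, order and place all loci of a genotype matrix.

    Pass ``groups`` to keep a previous group membership (used when
    re-mapping after curation masks calls).
    """
    if pairs is None:
        pairs = pairwise_r(gm, low_support_floor=min_support)
    if groups is None:
        groups, labels = group_markers(pairs, r_max=r_max,
                                       min_support=min_support)
    if labels is None:
        labels = [f"LG{i + 1}" for i in range(len(groups))]
    codes = gm.loci["code"].to_numpy()
    out = []
    for gid, (g, label) in enumerate(zip(groups, labels)):
        if len(g) < min_group_size:
            continue
        bins = build_bins(g, pairs, gm)
        order = order_markers(bins.representatives, pairs, codes=codes,
                              ripple_window=ripple_window)
        pos = map_positions(order, pairs, map_function, ril_correction)
        out.append(LinkageGroupMap(group_id=gid, label=label, loci=g,
                                   bins=bins, order=order, positions=pos))
    return LinkageMap(groups=out, map_function=map_function,
                      ril_correction=ril_correction), pairs


# ---------------------------------------------------------------------------
# rescue of distorted loci
# ---------------------------------------------------------------------------

def rescue_distorted(gm: GenotypeMatrix, pairs: RecPairs,
                     lmap: LinkageMap, skewed: np.ndarray,
                     gap_threshold: float = 20.0,
                     r_max: float = 0.2, min_support: int = 30,
                     map_function: str = "kosambi",
                     ril_correction: bool = True,
                     ripple_window: int = 5
                     ) -> Tuple[LinkageMap, pd.DataFrame]:
    """Re-admit skewed loci into groups that contain a large internal gap.

    For every group whose largest inter-marker gap exceeds
    ``gap_threshold`` cM, previously excluded allelically skewed loci
    that link (r̂ <= ``r_max`` with adequate support) to the group are
    added and the group re-binned and re-ordered.  Returns the updated
    map and a report of gaps before/after per group.
    """
    skewed = np.asarray(skewed, dtype=int)
    codes = gm.loci["code"].to_numpy()
    report = []
    new_groups = []
    for g in lmap.groups:
        gap_before = g.max_gap()
        if gap_before <= gap_threshold or len(skewed) == 0:
            new_groups.append(g)
            report.append({"group": g.label, "gap_before": gap_before,
                           "gap_after": gap_before, "n_rescued": 0})
            continue
        linked = []
        for s in skewed:
            r_to_group = pairs.r_hat[s, g.loci]
            inf = pairs.n_informative[s, g.loci]
            ok = (inf >= min_support) & (r_to_group <= r_max)
            if ok.any():
                linked.append(s)
        if not linked:
            new_groups.append(g)
            report.append({"group": g.label, "gap_before": gap_before,
                           "gap_after": gap_before, "n_rescued": 0})
            continue
        loci = np.concatenate((g.loci, np.array(linked, dtype=int)))
        bins = build_bins(loci, pairs, gm)
        order = order_markers(bins.representatives, pairs, codes=codes,
                              ripple_window=ripple_window)
        pos = map_positions(order, pairs, map_function, ril_correction)
        g2 = LinkageGroupMap(group_id=g.group_id, label=g.label, loci=loci,
                             bins=bins, order=order, positions=pos)
        new_groups.append(g2)
        report.append({"group": g.label, "gap_before": gap_before,
                       "gap_after": g2.max_gap(), "n_rescued": len(linked)})
    return (LinkageMap(groups=new_groups, map_function=map_function,
                       ril_correction=ril_correction),
            pd.DataFrame(report))
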