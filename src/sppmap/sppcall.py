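"""Single-position-polymorphism detection on tiled-array intensities.

A 2-bp window of a unigene is interrogated by up to 13 overlapping
25-mer probes.  For each chip, every probe's intensity is compared with
the chip's own *reference set value* — the mean genomic intensity of the
probe's GC bin — through the relative deviation

    SPPdev = |(I - ref) / I|

and the per-window statistic is the weighted mean of probe deviations,
weighted by a curve that decays with the distance of the probe centre
from the window.  Sorting the per-chip SPPdev values of a window and
searching for a gap larger than a user-set difference (default 0.2)
detects a bimodal split: chips on the far side of the gap carry the
allele that mismatches the probes.  Parental chips anchor the two sides
to the ``A`` and ``B`` alleles, and a RIL is called only when both of
its replicate chips fall on the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .simulate import (
    IntensityDataset,
    PROBE_HALF,
    PROBE_LEN,
    PROBE_STEP,
)

__all__ = [
    "MISSING",
    "GCBinStats",
    "WeightCurve",
    "WindowCalls",
    "RangeSet",
    "assign_gc_bins",
    "compute_gcbin_stats",
    "valid_probes",
    "sppdev_at_window",
    "detect_gap",
    "call_windows",
    "call_genotypes",
    "summarize_ranges",
    "filter_spps",
    "qc_cluster_chips",
]

#: genotype code for a missing call (A=0, B=1 as in :mod:`sppmap.simulate`)
MISSING = -1

#: probes overlap a 2-bp window when their centre is within this distance
MAX_PROBE_DIST = PROBE_HALF  # 12 bp


class EmptyBinError(ValueError):
    """A GC bin lacks the probes needed to compute its statistics."""


# ---------------------------------------------------------------------------
# GC bins, reference values, background cutoffs
# ---------------------------------------------------------------------------

def assign_gc_bins(probes: pd.DataFrame) -> pd.Series:
    """Map each probe to its GC bin (one bin per distinct GC count)."""
    gc = probes["gc_count"]
    if (gc < 0).any() or (gc > PROBE_LEN).any():
        raise ValueError("gc_count outside [0, 25]")
    return gc.astype(int)


@dataclass
class GCBinStats:
    """Per-chip, per-GC-bin reference values and background cutoffs."""

    bins: np.ndarray            # sorted distinct gc counts
    reference: np.ndarray       # (n_chips, n_bins) mean genomic intensity
    background_cutoff: np.ndarray  # (n_chips, n_bins) 90th pct anti-genomic
    bin_index: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bin_index:
            self.bin_index = {int(b): i for i, b in enumerate(self.bins)}


def compute_gcbin_stats(data: IntensityDataset,
                        bins: Optional[pd.Series] = None,
                        min_antigenomic: int = 10) -> GCBinStats:
    """Compute the reference set value and background cutoff per chip/bin.

    reference = mean intensity of genomic probes of the bin on that chip;
    cutoff = 90th percentile (linear interpolation) of the anti-genomic
    probes of the bin on that chip.
    """
    if bins is None:
        bins = assign_gc_bins(data.probes)
    gc = bins.to_numpy()
    genomic = ~data.probes["antigenomic"].to_numpy()
    present = np.unique(gc[genomic])
    X = data.intensities

    n_chips = X.shape[0]
    ref = np.empty((n_chips, len(present)))
    cut = np.empty((n_chips, len(present)))
    for i, b in enumerate(present):
        g_idx = np.flatnonzero(genomic & (gc == b))
        a_idx = np.flatnonzero(~genomic & (gc == b))
        if len(g_idx) == 0:
            raise EmptyBinError(f"GC bin {b} has no genomic probes")
        if len(a_idx) < min_antigenomic:
            raise EmptyBinError(
                f"GC bin {b} has only {len(a_idx)} anti-genomic probes "
                f"(need >= {min_antigenomic})"
            )
        ref[:, i] = X[:, g_idx].mean(axis=1)
        cut[:, i] = np.percentile(X[:, a_idx], 90, axis=1)
    return GCBinStats(bins=present, reference=ref, background_cutoff=cut)


def valid_probes(data: IntensityDataset, stats: GCBinStats,
                 bins: Optional[pd.Series] = None) -> np.ndarray:
    """Boolean (chips x probes) mask of probes above their background cutoff.

    A probe is excluded on a chip when its intensity is *less than* the
    90th percentile of the anti-genomic probes in its GC bin; equality
    keeps the probe.  Anti-genomic probes are never valid.
    """
    if bins is None:
        bins = assign_gc_bins(data.probes)
    gc = bins.to_numpy()
    genomic = ~data.probes["antigenomic"].to_numpy()
    col = np.array([stats.bin_index.get(int(b), -1) for b in gc])
    ok_bin = col >= 0
    cutoffs = np.zeros_like(data.intensities)
    cutoffs[:, ok_bin] = stats.background_cutoff[:, col[ok_bin]]
    mask = (data.intensities >= cutoffs) & genomic[None, :] & ok_bin[None, :]
    return mask


# ---------------------------------------------------------------------------
# weighting curve and SPPdev
# ---------------------------------------------------------------------------

@dataclass
class WeightCurve:
    """Positional weight of a probe as a function of centre-to-window distance.

    The default is triangular, ``weight(d) = max(0, 1 - |d|/13)``: maximal
    for a probe centred on the window and zero beyond 12 bp, matching the
    requirement that central probes dominate.  Any callable satisfying
    weight(0)=1, non-increasing in |d| and 0 beyond ``max_dist`` may be
    substituted.
    """

    func: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    max_dist: int = MAX_PROBE_DIST

    def __post_init__(self) -> None:
        if self.func is None:
            self.func = lambda d: np.clip(1.0 - np.abs(d) / (self.max_dist + 1),
                                          0.0, None)

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        w = np.where(np.abs(d) > self.max_dist, 0.0, self.func(d))
        return np.clip(w, 0.0, 1.0)


def _window_weight_matrix(n_probes: int, n_windows: int,
                          curve: WeightCurve) -> np.ndarray:
    """(n_windows x n_probes) weights; probe j overlaps window k when
    j in [k-12, k] (probe centres at 1+12+2j, window left bases at 1+2k)."""
    k = np.arange(n_windows)[:, None]
    j = np.arange(n_probes)[None, :]
    d = PROBE_HALF + PROBE_STEP * (j - k)
    return curve(d)


def _relative_deviation(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """|(I - ref) / I| elementwise; I > 0 by construction."""
    return np.abs((X - ref) / X)


@dataclass
class WindowCalls:
    """Per-window SPP detections with per-chip evidence and per-RIL calls."""

    windows: pd.DataFrame  # unigene_id, position, split_value, mean_sppdev,
                           # n_valid_probes, discarded, reason
    geno: np.ndarray       # (n_windows, n_rils) codes 0/1/-1
    ril_ids: np.ndarray
    sppdev: Optional[np.ndarray] = None  # (n_windows, n_chips), debug

    @property
    def n_polymorphic(self) -> int:
        return int((~self.windows["discarded"]).sum())


def _unigene_blocks(probes: pd.DataFrame):
    genomic = probes[~probes["antigenomic"]]
    for u, sub in genomic.groupby("unigene_id", sort=True):
        yield int(u), sub.index.to_numpy()


def compute_sppdev(data: IntensityDataset, stats: GCBinStats,
                   curve: Optional[WeightCurve] = None,
                   bins: Optional[pd.Series] = None,
                   valid: Optional[np.ndarray] = None
                   ) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Weighted SPPdev for every 2-bp window of every unigene.

    Returns ``(window_table, sppdev, n_valid)`` where ``sppdev`` is
    (n_windows x n_chips), NaN where a chip has no valid overlapping
    probe, and ``n_valid`` is the mean number of contributing probes per
    chip for each window.
    """
    if curve is None:
        curve = WeightCurve()
    if bins is None:
        bins = assign_gc_bins(data.probes)
    if valid is None:
        valid = valid_probes(data, stats, bins)
    gc = bins.to_numpy()
    col = np.array([stats.bin_index.get(int(b), 0) for b in gc])

    rows: List[Tuple[int, int]] = []
    spp_blocks: List[np.ndarray] = []
    nval_blocks: List[np.ndarray] = []
    W_cache: Dict[int, np.ndarray] = {}
    X = data.intensities
    for u, idx in _unigene_blocks(data.probes):
        P = len(idx)
        n_windows = P  # windows at left bases 1, 3, ..., 1+2(P-1)
        if P not in W_cache:
            W_cache[P] = _window_weight_matrix(P, n_windows, curve)
        W = W_cache[P]
        ref = stats.reference[:, col[idx]]           # chips x P
        dev = _relative_deviation(X[:, idx], ref)    # chips x P
        V = valid[:, idx].astype(float)              # chips x P
        num = (dev * V) @ W.T                        # chips x K
        den = V @ W.T
        with np.errstate(invalid="ignore", divide="ignore"):
            spp = np.where(den > 0, num / den, np.nan)
        nval = (V @ (W > 0).T.astype(float)).mean(axis=0)  # mean probes/chip
        positions = 1 + PROBE_STEP * np.arange(n_windows)
        rows.extend((u, int(p)) for p in positions)
        spp_blocks.append(spp.T)
        nval_blocks.append(nval)
    table = pd.DataFrame(rows, columns=["unigene_id", "position"])
    return table, np.vstack(spp_blocks), np.concatenate(nval_blocks)


def sppdev_at_window(data: IntensityDataset, stats: GCBinStats,
                     curve: WeightCurve, unigene: int,
                     position: int,
                     bins: Optional[pd.Series] = None,
                     valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-chip SPPdev at a single 2-bp window (NaN = no valid probe)."""
    if bins is None:
        bins = assign_gc_bins(data.probes)
    if valid is None:
        valid = valid_probes(data, stats, bins)
    gc = bins.to_numpy()
    col = np.array([stats.bin_index.get(int(b), 0) for b in gc])
    sub = data.probes[(data.probes["unigene_id"] == unigene)
                      & (~data.probes["antigenomic"])]
    idx = sub.index.to_numpy()
    d = sub["center_position"].to_numpy() - position
    w = curve(d)
    sel = w > 0
    idx, w = idx[sel], w[sel]
    if len(idx) == 0:
        raise ValueError(f"no probe overlaps window {position} of unigene {unigene}")
    ref = stats.reference[:, col[idx]]
    dev = _relative_deviation(data.intensities[:, idx], ref)
    V = valid[:, idx].astype(float)
    num = (dev * V) @ w
    den = V @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


# ---------------------------------------------------------------------------
# bimodal gap search and genotype assignment
# ---------------------------------------------------------------------------

def detect_gap(values: np.ndarray, delta: float) -> Optional[float]:
    """First gap larger than ``delta`` in ascending sorted values.

    Returns the midpoint of the gap, or None when no consecutive pair of
    sorted values differs by more than ``delta``.  NaNs are ignored.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return None
    gaps = np.diff(v)
    hits = np.flatnonzero(gaps > delta)
    if len(hits) == 0:
        return None
    i = hits[0]
    return float((v[i] + v[i + 1]) / 2.0)


def _detect_gaps_vec(spp: np.ndarray, delta: float) -> np.ndarray:
    """Vectorised gap search over (n_windows x n_chips); NaN = no split."""
    s = np.sort(spp, axis=1)  # NaNs sort to the end
    gaps = np.diff(s, axis=1)
    over = np.nan_to_num(gaps, nan=0.0) > delta
    has = over.any(axis=1)
    first = np.argmax(over, axis=1)
    split = np.full(spp.shape[0], np.nan)
    rows = np.flatnonzero(has)
    split[rows] = (s[rows, first[rows]] + s[rows, first[rows] + 1]) / 2.0
    return split


def call_genotypes(sppdev: np.ndarray, split: float,
                   chips: pd.DataFrame) -> Tuple[np.ndarray, Optional[str]]:
    """Assign per-RIL genotypes for one window given its gap midpoint.

    The gap side holding every parent-A chip is labelled ``A`` and the
    side holding every parent-B chip ``B``; a window whose parental chips
    straddle the gap (or are all missing) is discarded.  A RIL is called
    only when both replicate chips fall on the same side.
    Returns (calls over RILs, reason) where reason is None on success.
    """
    side = sppdev > split  # True = high-deviation side; NaN -> False, masked below
    ok = ~np.isnan(sppdev)
    src = chips["source"].to_numpy()
    pa = ok & (src == "parentA")
    pb = ok & (src == "parentB")
    if not pa.any() or not pb.any():
        return np.array([]), "parent-missing"
    if len(np.unique(side[pa])) > 1 or len(np.unique(side[pb])) > 1:
        return np.array([]), "parent-straddle"
    side_a = bool(side[pa][0])
    side_b = bool(side[pb][0])
    if side_a == side_b:
        return np.array([]), "parents-same-side"

    lines = chips["line"].to_numpy()
    ril_mask = src == "RIL"
    ril_ids = np.unique(lines[ril_mask])
    calls = np.full(len(ril_ids), MISSING, dtype=np.int8)
    for i, r in enumerate(ril_ids):
        reps = np.flatnonzero(ril_mask & (lines == r))
        if not ok[reps].all():
            continue
        sides = side[reps]
        if len(np.unique(sides)) == 1:
            calls[i] = 0 if bool(sides[0]) == side_a else 1
    return calls, None


def call_windows(data: IntensityDataset, stats: GCBinStats,
                 curve: Optional[WeightCurve] = None,
                 delta: float = 0.2,
                 bins: Optional[pd.Series] = None,
                 keep_sppdev: bool = False) -> WindowCalls:
    """Run the full window-level caller: SPPdev, gap search, genotypes."""
    table, spp, nval = compute_sppdev(data, stats, curve, bins)
    split = _detect_gaps_vec(spp, delta)

    src = data.chips["source"].to_numpy()
    lines = data.chips["line"].to_numpy()
    ril_mask = src == "RIL"
    ril_ids = np.unique(lines[ril_mask])
    rep_rows = {r: np.flatnonzero(ril_mask & (lines == r)) for r in ril_ids}
    pa_rows = np.flatnonzero(src == "parentA")
    pb_rows = np.flatnonzero(src == "parentB")

    n_win = len(table)
    geno = np.full((n_win, len(ril_ids)), MISSING, dtype=np.int8)
    discarded = np.ones(n_win, dtype=bool)
    reasons = np.full(n_win, "no-gap", dtype=object)
    mean_spp = np.nanmean(spp, axis=1)

    poly = np.flatnonzero(~np.isnan(split))
    for w in poly:
        side = spp[w] > split[w]
        ok = ~np.isnan(spp[w])
        pa_ok, pb_ok = ok[pa_rows], ok[pb_rows]
        if not pa_ok.any() or not pb_ok.any():
            reasons[w] = "parent-missing"
            continue
        sa = side[pa_rows][pa_ok]
        sb = side[pb_rows][pb_ok]
        if len(np.unique(sa)) > 1 or len(np.unique(sb)) > 1:
            reasons[w] = "parent-straddle"
            continue
        if bool(sa[0]) == bool(sb[0]):
            reasons[w] = "parents-same-side"
            continue
        side_a = bool(sa[0])
        discarded[w] = False
        reasons[w] = ""
        for i, r in enumerate(ril_ids):
            rows = rep_rows[r]
            if not ok[rows].all():
                continue
            s = side[rows]
            if len(np.unique(s)) == 1:
                geno[w, i] = 0 if bool(s[0]) == side_a else 1

    table = table.copy()
    table["split_value"] = split
    table["mean_sppdev"] = mean_spp
    table["n_valid_probes"] = nval
    table["discarded"] = discarded
    table["reason"] = reasons
    return WindowCalls(windows=table, geno=geno, ril_ids=ril_ids,
                       sppdev=spp if keep_sppdev else None)


# ---------------------------------------------------------------------------
# SPP ranges and filters
# ---------------------------------------------------------------------------

@dataclass
class RangeSet:
    """Contiguous runs of polymorphic windows with per-RIL consensus calls."""

    table: pd.DataFrame  # unigene_id, start, end, n_windows, mean_sppdev,
                         # n_valid_probes, missing_frac
    geno: np.ndarray     # (n_ranges, n_rils)
    ril_ids: np.ndarray


def _majority_call(calls: np.ndarray) -> int:
    """Majority of non-missing window calls; tie or all-missing -> missing."""
    a = int((calls == 0).sum())
    b = int((calls == 1).sum())
    if a == b:
        return MISSING
    return 0 if a > b else 1


def summarize_ranges(calls: WindowCalls) -> RangeSet:
    """Merge adjacent (2-bp-step) polymorphic windows into SPP ranges.

    The per-RIL genotype of a range is the majority of its window calls
    (ties and all-missing become missing).
    """
    win = calls.windows
    poly = win[~win["discarded"]]
    rows = []
    geno_rows = []
    for u, sub in poly.groupby("unigene_id", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        starts = np.flatnonzero(
            np.concatenate(([True], np.diff(pos) > PROBE_STEP)))
        bounds = np.concatenate((starts, [len(pos)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            widx = sub.index.to_numpy()[s:e]
            g = calls.geno[widx]
            consensus = np.array([_majority_call(g[:, i])
                                  for i in range(g.shape[1])], dtype=np.int8)
            rows.append({
                "unigene_id": u,
                "start": int(pos[s]),
                "end": int(pos[e - 1] + PROBE_STEP - 1),
                "n_windows": int(e - s),
                "mean_sppdev": float(sub["mean_sppdev"].to_numpy()[s:e].mean()),
                "n_valid_probes": float(
                    sub["n_valid_probes"].to_numpy()[s:e].mean()),
                "missing_frac": float(np.mean(consensus == MISSING)),
            })
            geno_rows.append(consensus)
    table = pd.DataFrame(rows, columns=[
        "unigene_id", "start", "end", "n_windows", "mean_sppdev",
        "n_valid_probes", "missing_frac"])
    geno = (np.vstack(geno_rows) if geno_rows
            else np.empty((0, len(calls.ril_ids)), dtype=np.int8))
    return RangeSet(table=table, geno=geno, ril_ids=calls.ril_ids)


def filter_spps(ranges: RangeSet,
                min_mean_sppdev: float = 0.2,
                max_missing_frac: float = 0.12,
                min_valid_probes: float = 3.0,
                min_span_bp: int = 2) -> Tuple[RangeSet, pd.DataFrame]:
    """Apply the four SPP-range retention criteria.

    Keeps ranges with mean SPPdev >= ``min_mean_sppdev``, missing-call
    fraction <= ``max_missing_frac``, mean valid probes >=
    ``min_valid_probes`` and span >= ``min_span_bp``.  Returns the kept
    ranges and a table of rejected ranges with reasons.
    """
    t = ranges.table
    span = t["end"] - t["start"] + 1
    reasons = np.full(len(t), "", dtype=object)
    reasons[t["mean_sppdev"].to_numpy() < min_mean_sppdev] = "low-sppdev"
    m = (t["missing_frac"].to_numpy() > max_missing_frac) & (reasons == "")
    reasons[m] = "missing"
    m = (t["n_valid_probes"].to_numpy() < min_valid_probes) & (reasons == "")
    reasons[m] = "few-probes"
    m = (span.to_numpy() < min_span_bp) & (reasons == "")
    reasons[m] = "short-span"
    keep = reasons == ""
    rejected = t[~keep].copy()
    rejected["reject_reason"] = reasons[~keep]
    kept = RangeSet(table=t[keep].reset_index(drop=True),
                    geno=ranges.geno[keep], ril_ids=ranges.ril_ids)
    return kept, rejected


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def qc_cluster_chips(data: IntensityDataset, n_top: int = 2000,
                     margin: float = 0.05) -> List[int]:
    """Flag RILs whose replicate chips do not cluster together.

    Chips are correlated (Pearson, log scale) over the ``n_top``
    highest-variance genomic probes.  A RIL is flagged when its
    replicate-pair correlation falls more than ``margin`` below the best
    correlation of either replicate to a chip outside the pair — i.e.
    the replicates clearly cluster apart.  The margin protects lines
    with little polymorphic signal (e.g. near-pure parental genomes),
    whose replicate correlation is baseline-level for benign reasons.
    """
    genomic = ~data.probes["antigenomic"].to_numpy()
    X = np.log(data.intensities[:, genomic])
    var = X.var(axis=0)
    top = np.argsort(var)[::-1][:min(n_top, X.shape[1])]
    C = np.corrcoef(X[:, top])
    np.fill_diagonal(C, -np.inf)

    src = data.chips["source"].to_numpy()
    lines = data.chips["line"].to_numpy()
    flagged = []
    for r in np.unique(lines[src == "RIL"]):
        rows = np.flatnonzero((src == "RIL") & (lines == r))
        if len(rows) < 2:
            continue
        sib = min(C[a, b] for i, a in enumerate(rows) for b in rows[i + 1:])
        outside = np.setdiff1d(np.arange(C.shape[0]), rows)
        cross = max(C[np.ix_(rows, outside)].max(), -1.0)
        if sib < cross - margin:
            flagged.append(int(r))
    return flagged
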