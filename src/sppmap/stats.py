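"""Map-level statistics and analytic expectations.

Covers segregation-distortion tests against the Mendelian 1:1 ratio
(heterozygotes excluded — the caller emits only A/B/missing), the
Poisson test for clustering of loci in 5-cM intervals, LD as r²,
crossover counting at fixed marker spacing, the closed-form
expectations for residual heterozygosity and crossover number in a
selfing pedigree, and cross-technology concordance arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sppcall import MISSING
from .linkage import GenotypeMatrix, LinkageMap

__all__ = [
    "DistortionResult",
    "distortion_test",
    "distortion_table",
    "poisson_interval_test",
    "ld_r2",
    "crossover_counts",
    "expected_residual_het",
    "expected_crossovers",
    "concordance",
    "allele_ratio_to_maf",
    "spp_density",
    "mean_spp_per_locus",
    "bin_summary",
]


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

@dataclass
class DistortionResult:
    n_a: int
    n_b: int
    chi2: float
    p: float
    direction: str       # toward-A / toward-B / none
    significant_05: bool
    significant_01: bool


def distortion_test(calls: np.ndarray) -> DistortionResult:
    """Goodness-of-fit χ² of one locus against the 1:1 expectation.

    chi2 = (nA - n/2)²/(n/2) + (nB - n/2)²/(n/2) on 1 df, no continuity
    correction; heterozygous and missing calls are excluded.
    """
    calls = np.asarray(calls)
    n_a = int((calls == 0).sum())
    n_b = int((calls == 1).sum())
    n = n_a + n_b
    if n == 0:
        raise ValueError("no informative calls at locus")
    e = n / 2.0
    chi2 = (n_a - e) ** 2 / e + (n_b - e) ** 2 / e
    p = float(sps.chi2.sf(chi2, df=1))
    if p < 0.05:
        direction = "toward-A" if n_a > n_b else "toward-B"
    else:
        direction = "none"
    return DistortionResult(n_a=n_a, n_b=n_b, chi2=float(chi2), p=p,
                            direction=direction,
                            significant_05=p < 0.05,
                            significant_01=p < 0.01)


def distortion_table(gm: GenotypeMatrix,
                     bonferroni: bool = False) -> pd.DataFrame:
    """Distortion test for every locus of a genotype matrix.

    ``bonferroni`` additionally flags loci at the family-wise 0.05 level;
    the per-locus raw thresholds are always reported.
    """
    rows = []
    m = gm.n_loci
    for i in range(m):
        try:
            r = distortion_test(gm.geno[i])
        except ValueError:
            rows.append({"code": gm.loci.loc[i, "code"], "n_a": 0, "n_b": 0,
                         "chi2": np.nan, "p": np.nan, "direction": "undefined",
                         "significant_05": False, "significant_01": False})
            continue
        rows.append({"code": gm.loci.loc[i, "code"], "n_a": r.n_a,
                     "n_b": r.n_b, "chi2": r.chi2, "p": r.p,
                     "direction": r.direction,
                     "significant_05": r.significant_05,
                     "significant_01": r.significant_01})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["significant_bonferroni"] = out["p"] < 0.05 / max(m, 1)
    return out


# ---------------------------------------------------------------------------
# Poisson clustering of loci along the map
# ---------------------------------------------------------------------------

def poisson_interval_test(positions_cm: np.ndarray,
                          group_length: Optional[float] = None,
                          interval: float = 5.0) -> Dict[str, float]:
    """χ² test of locus counts per fixed-width interval against Poisson.

    The group is divided into ``interval``-cM bins; the frequency-of-
    counts histogram is compared with Poisson(µ) expectations where µ is
    the mean count per interval.  Tail categories are pooled upward so
    that every expected frequency is at least 1.
    """
    pos = np.asarray(positions_cm, dtype=float)
    if group_length is None:
        group_length = float(pos.max()) if len(pos) else 0.0
    n_intervals = max(int(np.ceil(group_length / interval)), 1)
    if n_intervals < 5:
        raise ValueError("need at least 5 intervals for the Poisson test")
    counts = np.bincount(
        np.minimum((pos / interval).astype(int), n_intervals - 1),
        minlength=n_intervals)
    mu = counts.mean()

    max_x = counts.max()
    xs = np.arange(max_x + 1)
    pmf = sps.poisson.pmf(xs, mu)
    pmf = np.append(pmf, sps.poisson.sf(max_x, mu))  # tail: > max observed
    expected = pmf * n_intervals
    observed = np.append(np.bincount(counts, minlength=max_x + 1), 0)

    # pool adjacent categories (from the tail inward, then from the head)
    # until every expected frequency is >= 1
    obs_p: List[float] = list(observed)
    exp_p: List[float] = list(expected)
    i = len(exp_p) - 1
    while i > 0:
        if exp_p[i] < 1.0:
            exp_p[i - 1] += exp_p[i]
            obs_p[i - 1] += obs_p[i]
            del exp_p[i], obs_p[i]
        i -= 1
    if exp_p and exp_p[0] < 1.0 and len(exp_p) > 1:
        exp_p[1] += exp_p[0]
        obs_p[1] += obs_p[0]
        del exp_p[0], obs_p[0]
    obs_arr = np.asarray(obs_p, dtype=float)
    exp_arr = np.asarray(exp_p, dtype=float)
    # renormalise the tiny mass lost to pooling so the categories sum to n
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    dof = len(obs_arr) - 2  # mean estimated from the data
    if dof < 1:
        return {"chi2": 0.0, "p": 1.0, "mu": float(mu),
                "n_intervals": float(n_intervals), "dof": 0.0}
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    p = float(sps.chi2.sf(chi2, df=dof))
    return {"chi2": chi2, "p": p, "mu": float(mu),
            "n_intervals": float(n_intervals), "dof": float(dof)}


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(calls_i: np.ndarray, calls_j: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1-coded calls over complete RILs.

    Raises on monomorphic input (r² undefined).
    """
    ci = np.asarray(calls_i)
    cj = np.asarray(calls_j)
    ok = (ci != MISSING) & (cj != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 co-observed RILs")
    x = ci[ok].astype(float)
    y = cj[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic locus: r2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(gm: GenotypeMatrix, loci: np.ndarray) -> np.ndarray:
    """r² for all pairs of the selected loci (NaN where undefined)."""
    loci = np.asarray(loci, dtype=int)
    n = len(loci)
    out = np.full((n, n), np.nan)
    for a in range(n):
        out[a, a] = 1.0
        for b in range(a + 1, n):
            try:
                v = ld_r2(gm.geno[loci[a]], gm.geno[loci[b]])
            except ValueError:
                continue
            out[a, b] = out[b, a] = v
    return out


# ---------------------------------------------------------------------------
# crossover counting
# ---------------------------------------------------------------------------

def _grid_markers(g_order: np.ndarray, positions: np.ndarray,
                  miss: np.ndarray, codes: np.ndarray,
                  spacing: float) -> np.ndarray:
    """Representatives nearest each spacing-cM grid point.

    Ties on distance are broken by least missing data, then by code.
    """
    if len(positions) == 0:
        return np.array([], dtype=int)
    length = positions[-1]
    grid = np.arange(0.0, length + spacing / 2, spacing)
    chosen = []
    for gp in grid:
        d = np.abs(positions - gp)
        best = np.lexsort((codes[g_order], miss[g_order], d))[0]
        chosen.append(g_order[best])
    return np.unique(np.array(chosen, dtype=int))


def crossover_counts(gm: GenotypeMatrix, lmap: LinkageMap,
                     spacing: float = 5.0) -> pd.DataFrame:
    """Call transitions per RIL per group using ~evenly spaced markers.

    Markers nearest each ``spacing``-cM grid point are subsampled and,
    per RIL, transitions between consecutive non-missing calls counted.
    """
    miss = gm.missing_counts()
    codes = gm.loci["code"].to_numpy()
    rows = []
    for g in lmap.groups:
        sel = _grid_markers(g.order, g.positions, miss, codes, spacing)
        # keep map order
        order_pos = {l: i for i, l in enumerate(g.order)}
        sel = sel[np.argsort([order_pos[l] for l in sel])]
        sub = gm.geno[sel]
        for ri in range(gm.n_rils):
            calls = sub[:, ri]
            calls = calls[calls != MISSING]
            n_xo = int((np.diff(calls) != 0).sum()) if len(calls) > 1 else 0
            rows.append({"ril": int(gm.ril_ids[ri]), "group": g.label,
                         "crossovers": n_xo})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic expectations
# ---------------------------------------------------------------------------

def expected_residual_het(n_selfing_generations: int) -> float:
    """Expected residual heterozygosity (%) after g selfing generations.

    Heterozygosity halves each generation: 100 · (1/2)^g.  An F7 line
    (g = 6) retains 1.5625%.
    """
    if n_selfing_generations < 0:
        raise ValueError("generations must be >= 0")
    return 100.0 * 0.5 ** n_selfing_generations


def expected_crossovers(n_chromosomes: int, arms_per_chromosome: int = 2,
                        n_meioses: int = 6) -> float:
    """Expected detectable crossovers per RIL in a selfing pedigree.

    Assumes one crossover per chromosome arm per meiosis with the
    ability to detect new crossovers halving each generation of selfing:
    n_chrom · arms · Σ_{i=0}^{g-1} (1/2)^i.  Nine chromosomes, two arms
    and six meioses give 35.4375 (~35).
    """
    if n_chromosomes < 1 or arms_per_chromosome < 1 or n_meioses < 1:
        raise ValueError("inputs must be >= 1")
    geom = sum(0.5 ** i for i in range(n_meioses))
    return n_chromosomes * arms_per_chromosome * geom


def allele_ratio_to_maf(ratio: float) -> float:
    """Minor/major allele-count ratio -> minor allele frequency.

    ratio = minor/major, so MAF = ratio / (1 + ratio); the mapping
    threshold ratio 0.2 corresponds to MAF 0.1667.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return ratio / (1.0 + ratio)


# ---------------------------------------------------------------------------
# cross-technology concordance
# ---------------------------------------------------------------------------

def concordance(gm1: GenotypeMatrix, gm2: GenotypeMatrix
                ) -> Dict[str, float]:
    """Cell-wise agreement between two call matrices on shared loci/RILs.

    Loci are matched by unigene_id and RILs by id; only cells non-missing
    in both matrices are compared.
    """
    u1 = gm1.loci.set_index("unigene_id")
    shared_u = gm1.loci["unigene_id"][
        gm1.loci["unigene_id"].isin(gm2.loci["unigene_id"])].unique()
    shared_r = np.intersect1d(gm1.ril_ids, gm2.ril_ids)
    if len(shared_u) == 0 or len(shared_r) == 0:
        raise ValueError("no shared loci or RILs between matrices")
    idx1 = {int(u): i for i, u in enumerate(gm1.loci["unigene_id"])}
    idx2 = {int(u): i for i, u in enumerate(gm2.loci["unigene_id"])}
    r1 = {int(r): i for i, r in enumerate(gm1.ril_ids)}
    r2 = {int(r): i for i, r in enumerate(gm2.ril_ids)}
    rows1 = [idx1[int(u)] for u in shared_u]
    rows2 = [idx2[int(u)] for u in shared_u]
    cols1 = [r1[int(r)] for r in shared_r]
    cols2 = [r2[int(r)] for r in shared_r]
    m1 = gm1.geno[np.ix_(rows1, cols1)]
    m2 = gm2.geno[np.ix_(rows2, cols2)]
    both = (m1 != MISSING) & (m2 != MISSING)
    n_comp = int(both.sum())
    n_disc = int(((m1 != m2) & both).sum())
    pct = 100.0 * n_disc / n_comp if n_comp else float("nan")
    return {"n_comparisons": n_comp, "n_discordant": n_disc,
            "percent_discordant": pct,
            "percent_concordant": 100.0 - pct if n_comp else float("nan")}


# ---------------------------------------------------------------------------
# report arithmetic on summary counts
# ---------------------------------------------------------------------------

def spp_density(total_bases: int, n_spp: int) -> float:
    """Assayed bases per SPP (e.g. 21,920,928 bp / 303,359 SPPs ≈ 72)."""
    if n_spp <= 0:
        raise ValueError("n_spp must be positive")
    return total_bases / n_spp


def mean_spp_per_locus(n_spp: int, n_polymorphic_loci: int) -> float:
    """Average SPP count per polymorphic unigene."""
    if n_polymorphic_loci <= 0:
        raise ValueError("n_polymorphic_loci must be positive")
    return n_spp / n_polymorphic_loci


def bin_summary(table: pd.DataFrame) -> Dict[str, float]:
    """Totals and ratios from a per-group bin table.

    Expects columns ``n_markers, n_bins, bin_markers, n_super_bins,
    super_bin_markers, n_singletons``; returns total markers, the
    singleton percentage and mean loci per bin.
    """
    total = int(table["n_markers"].sum())
    singles = int(table["n_singletons"].sum())
    n_bins = int(table["n_bins"].sum())
    bin_markers = int(table["bin_markers"].sum())
    return {
        "total_markers": total,
        "singleton_pct": 100.0 * singles / total,
        "loci_per_bin": bin_markers / n_bins,
        "super_bin_pct": 100.0 * table["super_bin_markers"].sum() / total,
        "bin_pct": 100.0 * bin_markers / total,
    }
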