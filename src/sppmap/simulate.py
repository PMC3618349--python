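"""Simulation of an F7 RIL population and tiled-array hybridization data.

The simulator produces the two substrates the calling pipeline consumes —
a chip-by-probe matrix of normalized hybridization intensities and the
probe/chip metadata — together with the full ground truth (haplotype
mosaics, residual-heterozygosity tracts, crossover counts, polymorphic
sites) so that every downstream stage can be validated against a known
answer.

Model
-----
* Pedigree: an F1 between two fully homozygous parents (alleles ``A`` and
  ``B``) is selfed for ``n_generations`` by single-seed descent.  Each
  gamete receives a Poisson(L/100) number of crossovers per chromosome
  (Haldane model, no interference) placed uniformly in cM.
* Array: 25-mer probes tiled every 2 bp on alternating strands along each
  unigene, so up to 13 probes overlap any 2-bp window.  GC content per
  probe is Binomial(25, 0.5) clipped to [5, 20]; baseline intensity is
  linear in GC.  Anti-genomic control probes carry only background signal.
* Signal: intensity = gc_baseline x allele_factor x lognormal noise.  A
  probe overlapping a polymorphic 2-bp site loses a fraction
  ``signal_depression`` of its signal on chips whose line carries the
  mismatching (``B``) allele; heterozygous tracts get the mean of the two
  allele factors (DNA is bulked from many sibling plants, so both alleles
  contribute).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import json

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "IntensityDataset",
    "demo_config",
    "simulate_pedigree",
    "design_probes",
    "simulate_intensities",
    "simulate_dataset",
    "meiosis",
    "PROBE_LEN",
    "PROBE_STEP",
    "GENOTYPE_A",
    "GENOTYPE_B",
    "GENOTYPE_H",
]

PROBE_LEN = 25
PROBE_STEP = 2
#: half-width of a 25-mer around its central base
PROBE_HALF = (PROBE_LEN - 1) // 2

# integer genotype codes used throughout the package
GENOTYPE_A = 0
GENOTYPE_B = 1
GENOTYPE_H = 2
GENOTYPE_CODES = np.array(["A", "B", "H"])


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the simulated population and array experiment.

    Defaults mirror the reference experiment: 213 F7 RILs over nine
    chromosomes with the published linkage-group sizes, duplicate chips
    per RIL and four chips per parent, ~20 polymorphic 2-bp sites per
    polymorphic unigene and a 50% hybridization-signal loss on the
    mismatching allele.  The number of unigenes is a size knob, not a
    study condition; the full 35,628-unigene array is far larger than
    any validation requires.
    """

    n_rils: int = 213
    n_chromosomes: int = 9
    chrom_lengths: Tuple[float, ...] = (
        144.0, 152.0, 174.0, 234.0, 234.0, 142.5, 142.0, 204.0, 158.5,
    )
    n_unigenes: int = 900
    unigene_length: int = 400
    #: genetic extent of one unigene in cM; non-zero so that recombination
    #: can fall inside a transcript (the 3% split-locus phenomenon)
    unigene_cm_span: float = 0.007
    #: fraction of unigenes carrying any polymorphism between the parents
    frac_polymorphic: float = 0.5
    #: probability that a 2-bp window of a polymorphic unigene is an SPP site
    spp_rate: float = 0.1
    signal_depression: float = 0.5
    noise_sd: float = 0.1
    #: slope of the linear GC -> baseline multiplier, centred at GC=12.5
    gc_effect: float = 0.03
    n_generations: int = 6
    replicate_chips_per_ril: int = 2
    parent_chips: int = 4
    #: anti-genomic background probes per GC level
    antigenomic_per_gc: int = 60
    baseline_intensity: float = 1000.0
    #: background median as a fraction of the genomic baseline (one order
    #: of magnitude below)
    background_scale: float = 0.1
    background_sd: float = 0.5
    #: number of RIL chips whose intensities are partially shuffled, to
    #: exercise replicate QC
    n_bad_chips: int = 0
    bad_chip_shuffle_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_rils < 1 or self.n_chromosomes < 1 or self.n_unigenes < 1:
            raise ConfigurationError("counts must be >= 1")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigurationError(
                f"chrom_lengths has {len(self.chrom_lengths)} entries for "
                f"{self.n_chromosomes} chromosomes"
            )
        if any(L <= 0 for L in self.chrom_lengths):
            raise ConfigurationError("chromosome lengths must be positive cM")
        for name in ("spp_rate", "signal_depression", "frac_polymorphic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.unigene_length < PROBE_LEN:
            raise ConfigurationError(
                f"unigene_length must be >= {PROBE_LEN} to fit one probe"
            )
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.replicate_chips_per_ril < 1 or self.parent_chips < 1:
            raise ConfigurationError("chip counts must be >= 1")


def demo_config(seed: int = 0) -> SimConfig:
    """Small two-chromosome configuration used for end-to-end validation.

    40 RILs, 2 chromosomes of 120 cM, 300 unigenes of 400 bp with ~20
    SPP sites per polymorphic unigene, 50% signal depression and 0.1
    log-scale noise.
    """
    return SimConfig(
        n_rils=40,
        n_chromosomes=2,
        chrom_lengths=(120.0, 120.0),
        n_unigenes=300,
        unigene_length=400,
        frac_polymorphic=0.5,
        spp_rate=0.1,
        signal_depression=0.5,
        noise_sd=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

Homolog = Tuple[np.ndarray, np.ndarray]  # (segment start positions, origins)


def _simplify(breaks: np.ndarray, codes: np.ndarray) -> Homolog:
    """Merge adjacent segments with identical codes."""
    if len(codes) <= 1:
        return breaks, codes
    keep = np.empty(len(codes), dtype=bool)
    keep[0] = True
    keep[1:] = codes[1:] != codes[:-1]
    return breaks[keep], codes[keep]


def _origin_at(h: Homolog, pos: np.ndarray) -> np.ndarray:
    breaks, codes = h
    idx = np.searchsorted(breaks, pos, side="right") - 1
    return codes[idx]


def meiosis(h1: Homolog, h2: Homolog, length_cm: float,
            rng: np.random.Generator) -> Tuple[Homolog, int]:
    """Produce one gamete from a pair of homologs.

    Crossovers per chromosome are Poisson(length in Morgans) with
    positions uniform on [0, L) — the Haldane no-interference model.
    Returns the gamete and the number of crossovers drawn.
    """
    if length_cm <= 0:
        raise ConfigurationError("chromosome length must be positive")
    k = int(rng.poisson(length_cm / 100.0))
    xs = np.sort(rng.uniform(0.0, length_cm, size=k))
    start = int(rng.integers(2))
    # breakpoints where the gamete switches template homolog
    seg_starts = np.concatenate(([0.0], xs))
    templates = (start + np.arange(k + 1)) % 2
    out_breaks: List[float] = []
    out_codes: List[int] = []
    for i, (s, t) in enumerate(zip(seg_starts, templates)):
        e = seg_starts[i + 1] if i + 1 < len(seg_starts) else length_cm
        if e <= s:
            continue
        h = h1 if t == 0 else h2
        breaks, codes = h
        j0 = np.searchsorted(breaks, s, side="right") - 1
        j1 = np.searchsorted(breaks, e, side="left")
        sub_breaks = np.concatenate(([s], breaks[j0 + 1:j1]))
        sub_codes = codes[j0:j1]
        out_breaks.extend(sub_breaks)
        out_codes.extend(sub_codes)
    gb, gc_ = _simplify(np.asarray(out_breaks), np.asarray(out_codes, dtype=np.int8))
    return (gb, gc_), k


def _diploid_segments(h1: Homolog, h2: Homolog) -> Tuple[np.ndarray, np.ndarray]:
    """Merge two homologs into genotype segments coded A/B/H."""
    breaks = np.union1d(h1[0], h2[0])
    o1 = _origin_at(h1, breaks)
    o2 = _origin_at(h2, breaks)
    codes = np.where(o1 == o2, o1, GENOTYPE_H).astype(np.int8)
    return _simplify(breaks, codes)


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    ``genotypes[(line, chrom)]`` holds the diploid genotype mosaic of a
    line as ``(segment_starts_cm, codes)`` with codes 0=A, 1=B, 2=H.
    Lines are RIL indices ``0..n_rils-1``; parents are the virtual lines
    ``"PA"`` / ``"PB"`` handled by :meth:`genotype_at`.
    """

    config: SimConfig
    genotypes: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]]
    het_regions: pd.DataFrame  # line, chrom, start_cm, end_cm
    unigene_positions: pd.DataFrame  # unigene_id, chrom, cm, span, polymorphic
    spp_sites: Dict[int, np.ndarray]  # unigene_id -> window left bases (1-based)
    crossover_count: np.ndarray  # (n_rils, n_chromosomes)
    bad_chips: List[str] = field(default_factory=list)

    def genotype_at(self, line, chrom: int, pos_cm: np.ndarray) -> np.ndarray:
        pos_cm = np.atleast_1d(np.asarray(pos_cm, dtype=float))
        if line == "PA":
            return np.full(len(pos_cm), GENOTYPE_A, dtype=np.int8)
        if line == "PB":
            return np.full(len(pos_cm), GENOTYPE_B, dtype=np.int8)
        breaks, codes = self.genotypes[(int(line), int(chrom))]
        idx = np.searchsorted(breaks, pos_cm, side="right") - 1
        return codes[idx]

    def unigene_genotype_matrix(self) -> np.ndarray:
        """(n_unigenes x n_rils) genotype codes at each unigene midpoint."""
        cfg = self.config
        out = np.empty((len(self.unigene_positions), cfg.n_rils), dtype=np.int8)
        for chrom, sub in self.unigene_positions.groupby("chrom"):
            pos = sub["cm"].to_numpy()
            rows = sub.index.to_numpy()
            for ril in range(cfg.n_rils):
                out[rows, ril] = self.genotype_at(ril, chrom, pos)
        return out

    def het_fraction(self) -> float:
        """Fraction of (unigene, RIL) genotype calls that are heterozygous."""
        m = self.unigene_genotype_matrix()
        return float(np.mean(m == GENOTYPE_H))

    def site_positions_cm(self, unigene_id: int) -> np.ndarray:
        """Genetic positions of the SPP sites of one unigene."""
        row = self.unigene_positions.loc[unigene_id]
        sites = self.spp_sites.get(unigene_id, np.empty(0, dtype=int))
        frac = (sites + 0.5) / self.config.unigene_length - 0.5
        return row["cm"] + frac * row["span"]


def simulate_pedigree(config: SimConfig) -> SimTruth:
    """Simulate the selfing pedigree and lay out unigenes and SPP sites.

    The F1 is heterozygous everywhere; each of ``n_generations`` selfing
    rounds draws two independent gametes per line (single-seed descent).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    genotypes: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}
    het_rows = []
    xo = np.zeros((cfg.n_rils, cfg.n_chromosomes), dtype=int)
    for ril in range(cfg.n_rils):
        for chrom, L in enumerate(cfg.chrom_lengths):
            h1: Homolog = (np.array([0.0]), np.array([GENOTYPE_A], dtype=np.int8))
            h2: Homolog = (np.array([0.0]), np.array([GENOTYPE_B], dtype=np.int8))
            for _ in range(cfg.n_generations):
                g1, _ = meiosis(h1, h2, L, rng)
                g2, _ = meiosis(h1, h2, L, rng)
                h1, h2 = g1, g2
            breaks, codes = _diploid_segments(h1, h2)
            genotypes[(ril, chrom)] = (breaks, codes)
            xo[ril, chrom] = len(codes) - 1
            ends = np.concatenate((breaks[1:], [L]))
            for s, e, c in zip(breaks, ends, codes):
                if c == GENOTYPE_H:
                    het_rows.append((ril, chrom, float(s), float(e)))

    het_regions = pd.DataFrame(
        het_rows, columns=["line", "chrom", "start_cm", "end_cm"]
    )

    # unigene layout: uniform random positions over the genome, weighted by
    # chromosome length
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    chrom_of = rng.choice(cfg.n_chromosomes, size=cfg.n_unigenes, p=probs)
    half_span = cfg.unigene_cm_span / 2.0
    cm_of = np.array([
        rng.uniform(half_span, lengths[c] - half_span) for c in chrom_of
    ])
    polymorphic = rng.random(cfg.n_unigenes) < cfg.frac_polymorphic
    unigene_positions = pd.DataFrame({
        "unigene_id": np.arange(cfg.n_unigenes),
        "chrom": chrom_of,
        "cm": cm_of,
        "span": cfg.unigene_cm_span,
        "polymorphic": polymorphic,
    }).set_index("unigene_id", drop=False)
    unigene_positions.index.name = None

    n_windows = cfg.unigene_length // PROBE_STEP
    spp_sites: Dict[int, np.ndarray] = {}
    for u in range(cfg.n_unigenes):
        if not polymorphic[u]:
            continue
        hit = rng.random(n_windows) < cfg.spp_rate
        # window m has left base 1 + 2m (1-based)
        sites = 1 + PROBE_STEP * np.flatnonzero(hit)
        if len(sites):
            spp_sites[u] = sites
        else:
            unigene_positions.loc[u, "polymorphic"] = False

    return SimTruth(
        config=cfg,
        genotypes=genotypes,
        het_regions=het_regions,
        unigene_positions=unigene_positions,
        spp_sites=spp_sites,
        crossover_count=xo,
    )


# ---------------------------------------------------------------------------
# array design
# ---------------------------------------------------------------------------

def design_probes(config: SimConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tile 25-mer probes every 2 bp on alternating strands per unigene.

    Returns a probe table with columns ``probe_id, unigene_id,
    center_position, strand, gc_count, antigenomic``.  Anti-genomic
    background probes (``unigene_id = -1``) are appended for every GC
    level in [5, 20].
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cfg = config
    n_per_unigene = (cfg.unigene_length - PROBE_LEN) // PROBE_STEP + 1
    j = np.arange(n_per_unigene)
    centers = 1 + PROBE_HALF + PROBE_STEP * j
    strands = np.where(j % 2 == 0, "+", "-")

    unigene_id = np.repeat(np.arange(cfg.n_unigenes), n_per_unigene)
    center = np.tile(centers, cfg.n_unigenes)
    strand = np.tile(strands, cfg.n_unigenes)
    n_genomic = len(unigene_id)
    gc = np.clip(rng.binomial(PROBE_LEN, 0.5, size=n_genomic), 5, 20)

    frames = [pd.DataFrame({
        "unigene_id": unigene_id,
        "center_position": center,
        "strand": strand,
        "gc_count": gc.astype(np.int16),
        "antigenomic": False,
    })]
    if cfg.antigenomic_per_gc > 0:
        ag_gc = np.repeat(np.arange(5, 21), cfg.antigenomic_per_gc)
        frames.append(pd.DataFrame({
            "unigene_id": -1,
            "center_position": 0,
            "strand": ".",
            "gc_count": ag_gc.astype(np.int16),
            "antigenomic": True,
        }))
    probes = pd.concat(frames, ignore_index=True)
    probes.insert(0, "probe_id", np.arange(len(probes)))
    return probes


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------

@dataclass
class IntensityDataset:
    """Normalized chip-by-probe intensities with probe and chip metadata."""

    intensities: np.ndarray  # (n_chips, n_probes), positive
    chips: pd.DataFrame      # chip_id, source, line, replicate
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape != (len(self.chips), len(self.probes)):
            raise ValueError("intensity matrix shape does not match metadata")
        if not self.chips["chip_id"].is_unique:
            raise ValueError("chip_ids must be unique")

    @property
    def n_rils(self) -> int:
        src = self.chips
        return int(src.loc[src["source"] == "RIL", "line"].nunique())


def _chip_manifest(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for ril in range(cfg.n_rils):
        for rep in range(cfg.replicate_chips_per_ril):
            rows.append((f"RIL{ril:04d}_r{rep + 1}", "RIL", ril, rep + 1))
    for parent, tag in (("parentA", "PA"), ("parentB", "PB")):
        for rep in range(cfg.parent_chips):
            rows.append((f"{tag}_r{rep + 1}", parent, -1, rep + 1))
    return pd.DataFrame(rows, columns=["chip_id", "source", "line", "replicate"])


def gc_baseline(gc_count: np.ndarray, config: SimConfig) -> np.ndarray:
    """Baseline intensity as a linear function of probe GC count."""
    mult = 1.0 + config.gc_effect * (np.asarray(gc_count, dtype=float) - 12.5)
    return config.baseline_intensity * np.clip(mult, 0.05, None)


def _line_allele_factors(truth: SimTruth, probes: pd.DataFrame,
                         line) -> np.ndarray:
    """Per-genomic-probe allele factor for one line (or parent tag).

    Each polymorphic 2-bp site multiplies the signal of the <=13 probes
    that overlap it by (1 - depression) on a B allele and by
    (1 - depression/2) on a heterozygous tract.
    """
    cfg = truth.config
    genomic = probes[~probes["antigenomic"]]
    n_per_unigene = (cfg.unigene_length - PROBE_LEN) // PROBE_STEP + 1
    factors = np.ones(len(genomic))
    d = cfg.signal_depression
    offset = 0
    for u in range(cfg.n_unigenes):
        sites = truth.spp_sites.get(u)
        if sites is not None and len(sites):
            row = truth.unigene_positions.loc[u]
            pos_cm = truth.site_positions_cm(u)
            geno = truth.genotype_at(line, int(row["chrom"]), pos_cm)
            m = (sites - 1) // PROBE_STEP  # window index of each site
            for mi, g in zip(m, geno):
                if g == GENOTYPE_A:
                    continue
                f = (1.0 - d) if g == GENOTYPE_B else (1.0 - d / 2.0)
                lo = max(0, mi - (PROBE_LEN // PROBE_STEP))
                hi = min(n_per_unigene, mi + 1)
                factors[offset + lo:offset + hi] *= f
        offset += n_per_unigene
    return factors


def simulate_intensities(truth: SimTruth, probes: pd.DataFrame,
                         config: SimConfig) -> IntensityDataset:
    """Generate the normalized intensity matrix for all chips.

    intensity = gc_baseline x allele_factor x lognormal(0, noise_sd).
    Anti-genomic probes draw from a lognormal background whose median is
    ``background_scale`` times the genomic baseline of their GC level.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    chips = _chip_manifest(cfg)
    genomic_mask = ~probes["antigenomic"].to_numpy()
    base = gc_baseline(probes["gc_count"].to_numpy(), cfg)

    n_chips = len(chips)
    n_probes = len(probes)
    X = np.empty((n_chips, n_probes))

    factor_cache: Dict[object, np.ndarray] = {}
    for i, row in chips.iterrows():
        line = row["line"] if row["source"] == "RIL" else (
            "PA" if row["source"] == "parentA" else "PB")
        if line not in factor_cache:
            factor_cache[line] = _line_allele_factors(truth, probes, line)
        mean = base.copy()
        mean[genomic_mask] *= factor_cache[line]
        # anti-genomic: background draw, median an order of magnitude lower
        mean[~genomic_mask] = base[~genomic_mask] * cfg.background_scale
        sd = np.where(genomic_mask, cfg.noise_sd, cfg.background_sd)
        noise = rng.normal(0.0, 1.0, size=n_probes) * sd
        X[i] = mean * np.exp(noise)

    data = IntensityDataset(intensities=X, chips=chips, probes=probes.copy())

    if cfg.n_bad_chips > 0:
        ril_rows = chips.index[chips["source"] == "RIL"].to_numpy()
        bad = rng.choice(ril_rows, size=cfg.n_bad_chips, replace=False)
        for b in bad:
            n_shuf = int(cfg.bad_chip_shuffle_frac * n_probes)
            idx = rng.choice(n_probes, size=n_shuf, replace=False)
            X[b, idx] = X[b, rng.permutation(idx)]
            truth.bad_chips.append(chips.loc[b, "chip_id"])
    return data


def simulate_dataset(config: SimConfig) -> Tuple[SimTruth, IntensityDataset]:
    """Run the full simulator: pedigree, probe design, intensities."""
    truth = simulate_pedigree(config)
    probes = design_probes(config)
    data = simulate_intensities(truth, probes, config)
    return truth, data


# ---------------------------------------------------------------------------
# oracle comparisons
# ---------------------------------------------------------------------------

def genotype_concordance(truth: SimTruth, unigene_ids: np.ndarray,
                         geno: np.ndarray,
                         ril_ids: np.ndarray) -> Dict[str, float]:
    """Agreement of locus calls with the simulated truth.

    Calls are A/B/missing; cells where the truth is heterozygous cannot
    be represented by the caller and are tallied separately rather than
    counted against it.  Returns concordance over (call non-missing,
    truth homozygous) cells plus bookkeeping counts.
    """
    tm = truth.unigene_genotype_matrix()
    agree = total = het_cells = 0
    for row, u in enumerate(unigene_ids):
        t = tm[int(u)][np.asarray(ril_ids, dtype=int)]
        c = geno[row]
        called = c >= 0
        het_cells += int((called & (t == GENOTYPE_H)).sum())
        ok = called & (t != GENOTYPE_H)
        total += int(ok.sum())
        agree += int((c[ok] == t[ok]).sum())
    return {
        "n_compared": total,
        "n_agree": agree,
        "concordance_pct": 100.0 * agree / total if total else float("nan"),
        "n_truth_het_called": het_cells,
    }


def order_recovery(truth: SimTruth, unigene_ids: np.ndarray,
                   positions: np.ndarray) -> float:
    """|Kendall tau| between inferred positions and true cM positions."""
    from scipy.stats import kendalltau

    true_cm = truth.unigene_positions.loc[
        np.asarray(unigene_ids, dtype=int), "cm"].to_numpy()
    tau = kendalltau(positions, true_cm).statistic
    return float(abs(tau))


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_dataset(data: IntensityDataset, truth: SimTruth, outdir) -> None:
    """Write intensities, probe table, chip manifest and truth bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inten = pd.DataFrame(
        data.intensities.T, columns=data.chips["chip_id"].tolist()
    )
    inten.insert(0, "probe_id", data.probes["probe_id"].to_numpy())
    inten.to_csv(out / "intensities.tsv", sep="\t", index=False,
                 float_format="%.4f")
    data.probes.to_csv(out / "probes.tsv", sep="\t", index=False)
    data.chips.to_csv(out / "chips.tsv", sep="\t", index=False)
    truth.het_regions.to_csv(out / "truth_het_regions.tsv", sep="\t", index=False)
    truth.unigene_positions.to_csv(out / "truth_unigenes.tsv", sep="\t",
                                   index=False)
    bundle = {
        "spp_sites": {str(k): v.tolist() for k, v in truth.spp_sites.items()},
        "crossover_count": truth.crossover_count.tolist(),
        "bad_chips": truth.bad_chips,
    }
    (out / "truth.json").write_text(json.dumps(bundle))


def read_dataset(indir) -> IntensityDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    ind = Path(indir)
    inten = pd.read_csv(ind / "intensities.tsv", sep="\t")
    probes = pd.read_csv(ind / "probes.tsv", sep="\t")
    chips = pd.read_csv(ind / "chips.tsv", sep="\t")
    X = inten.drop(columns=["probe_id"]).to_numpy().T
    return IntensityDataset(intensities=X, chips=chips, probes=probes)
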