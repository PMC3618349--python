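"""End-to-end pipeline: simulate -> call -> map -> curate -> stats -> export.

One configuration object (flat ``key = value`` pairs under ``[section]``
headers, INI style) drives every stage; a single global seed feeds all
randomness.  The resolved configuration is echoed to a provenance file
and every written output is checksummed into the run report, so two
runs with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import curation, export, haplotype, linkage, simulate, sppcall
from . import stats as mapstats
from .sppcall import MISSING

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "call_string",
    "parse_call_string",
    "write_loci",
    "read_loci",
]

log = logging.getLogger("sppmap")

_CALL_CHARS = {0: "A", 1: "B", MISSING: "-"}
_CHAR_CALLS = {v: k for k, v in _CALL_CHARS.items()}


def call_string(calls: np.ndarray) -> str:
    return "".join(_CALL_CHARS[int(c)] for c in calls)


def parse_call_string(s: str) -> np.ndarray:
    return np.array([_CHAR_CALLS[c] for c in s], dtype=np.int8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SIM_KEYS = {f.name for f in dataclasses.fields(simulate.SimConfig)}

_KNOWN_KEYS = {
    "global": {"seed", "outdir", "verbosity"},
    "simulate": _SIM_KEYS | {"demo"},
    "sppcall": {"delta", "min_mean_sppdev", "max_missing_frac",
                "min_valid_probes", "min_span_bp"},
    "haplotype": {"min_split_support"},
    "linkage": {"r_max", "min_support", "map_function", "ril_correction",
                "max_missing_rils", "min_allele_ratio", "ripple_window",
                "gap_threshold"},
    "curation": {"cluster_min"},
    "stats": {"spacing", "ld_interval"},
    "export": {"bp_per_cm", "locus_length", "min_spacer"},
}

_FLOAT_KEYS = {"delta", "min_mean_sppdev", "max_missing_frac",
               "min_valid_probes", "r_max", "min_allele_ratio",
               "gap_threshold", "spacing", "ld_interval",
               "spp_rate", "signal_depression", "noise_sd", "gc_effect",
               "frac_polymorphic", "unigene_cm_span", "baseline_intensity",
               "background_scale", "background_sd", "bad_chip_shuffle_frac"}
_BOOL_KEYS = {"ril_correction", "demo"}


@dataclass
class PipelineConfig:
    """Validated nested pipeline parameters with a single global seed."""

    seed: int = 0
    outdir: str = "sppmap_out"
    verbosity: str = "info"
    sections: Dict[str, Dict[str, object]] = field(default_factory=dict)

    def get(self, section: str, key: str, default):
        return self.sections.get(section, {}).get(key, default)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        cfg = cls()
        for section in cp.sections():
            if section not in _KNOWN_KEYS:
                raise ValueError(f"unknown config section [{section}]")
            for key, raw in cp.items(section):
                if key not in _KNOWN_KEYS[section]:
                    raise ValueError(
                        f"unknown key {key!r} in section [{section}]")
                cfg.sections.setdefault(section, {})[key] = _coerce(key, raw)
        g = cfg.sections.pop("global", {})
        cfg.seed = int(g.get("seed", cfg.seed))
        cfg.outdir = str(g.get("outdir", cfg.outdir))
        cfg.verbosity = str(g.get("verbosity", cfg.verbosity))
        return cfg

    def resolved_text(self) -> str:
        lines = ["[global]", f"seed = {self.seed}", f"outdir = {self.outdir}",
                 f"verbosity = {self.verbosity}"]
        for section in sorted(self.sections):
            lines.append(f"[{section}]")
            for key in sorted(self.sections[section]):
                lines.append(f"{key} = {self.sections[section][key]}")
        return "\n".join(lines) + "\n"

    def sim_config(self) -> simulate.SimConfig:
        sec = dict(self.sections.get("simulate", {}))
        demo = bool(sec.pop("demo", False))
        base = simulate.demo_config(self.seed) if demo else \
            simulate.SimConfig(seed=self.seed)
        overrides = {k: v for k, v in sec.items()}
        if "chrom_lengths" in overrides:
            cl = tuple(float(x) for x in str(overrides["chrom_lengths"]).split(","))
            overrides["chrom_lengths"] = cl
        cfg = dataclasses.replace(base, **overrides)
        return dataclasses.replace(cfg, seed=self.seed)


def _coerce(key: str, raw: str):
    raw = raw.strip()
    if key in _BOOL_KEYS:
        return raw.lower() in ("1", "true", "yes", "on")
    if key == "chrom_lengths":
        return raw
    if key in _FLOAT_KEYS:
        return float(raw)
    try:
        return int(raw)
    except ValueError:
        return raw


# ---------------------------------------------------------------------------
# locus table serialization
# ---------------------------------------------------------------------------

def write_loci(loci: haplotype.LocusSet, path) -> None:
    t = loci.table.copy()
    t["calls"] = [call_string(row) for row in loci.geno]
    t.to_csv(path, sep="\t", index=False)


def read_loci(path) -> haplotype.LocusSet:
    t = pd.read_csv(path, sep="\t")
    geno = np.vstack([parse_call_string(s) for s in t["calls"]]) \
        if len(t) else np.empty((0, 0), dtype=np.int8)
    ril_ids = np.arange(geno.shape[1] if len(t) else 0)
    return haplotype.LocusSet(table=t.drop(columns=["calls"]), geno=geno,
                              ril_ids=ril_ids)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 write_files: bool = True) -> Dict[str, object]:
    """Execute all stages in order and return the run report.

    The report carries per-stage counts (windows tested, SPP windows and
    ranges, loci, bins/super-bins/singletons per group, map lengths at
    the three curation stages, distortion fraction, crossover summary)
    plus SHA-256 checksums of every file written.
    """
    t0 = time.time()
    out = Path(config.outdir)
    report: Dict[str, object] = {"seed": config.seed, "stages": {}}
    if write_files:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_resolved.ini").write_text(config.resolved_text())

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    # --- simulate -----------------------------------------------------
    st = stage("simulate")
    sim_cfg = config.sim_config()
    truth, data = simulate.simulate_dataset(sim_cfg)
    st["n_rils"] = sim_cfg.n_rils
    st["n_chips"] = int(len(data.chips))
    st["n_probes"] = int(len(data.probes))
    st["n_polymorphic_unigenes"] = int(len(truth.spp_sites))
    st["true_total_cm"] = float(sum(sim_cfg.chrom_lengths))
    if write_files:
        simulate.write_dataset(data, truth, out / "simulated")

    # --- sppcall ------------------------------------------------------
    st = stage("sppcall")
    delta = float(config.get("sppcall", "delta", 0.2))
    bins = sppcall.assign_gc_bins(data.probes)
    gstats = sppcall.compute_gcbin_stats(data, bins)
    flagged = sppcall.qc_cluster_chips(data)
    calls = sppcall.call_windows(data, gstats, delta=delta, bins=bins)
    ranges = sppcall.summarize_ranges(calls)
    kept, rejected = sppcall.filter_spps(
        ranges,
        min_mean_sppdev=float(config.get("sppcall", "min_mean_sppdev", 0.2)),
        max_missing_frac=float(config.get("sppcall", "max_missing_frac", 0.12)),
        min_valid_probes=float(config.get("sppcall", "min_valid_probes", 3.0)),
        min_span_bp=int(config.get("sppcall", "min_span_bp", 2)))
    st["windows_tested"] = int(len(calls.windows))
    st["spp_windows"] = int(calls.n_polymorphic)
    st["spp_ranges"] = int(len(ranges.table))
    st["spp_ranges_kept"] = int(len(kept.table))
    st["qc_flagged_rils"] = flagged
    if write_files:
        t = kept.table.copy()
        t["calls"] = [call_string(row) for row in kept.geno]
        t.to_csv(out / "spp_ranges.tsv", sep="\t", index=False,
                 float_format="%.4f")
        calls.windows.to_csv(out / "spp_windows_debug.tsv", sep="\t",
                             index=False, float_format="%.4f")

    # --- haplotype ----------------------------------------------------
    st = stage("haplotype")
    loci = haplotype.build_loci(
        kept, min_split_support=int(config.get("haplotype",
                                               "min_split_support", 2)))
    st["n_loci"] = int(len(loci.table))
    st["n_split_unigenes"] = int(
        (loci.table["part"] != "whole").sum() // 2)
    if write_files:
        write_loci(loci, out / "loci.tsv")
        haplotype.conversion_table(loci).to_csv(
            out / "locus_codes.tsv", sep="\t", index=False)

    # --- linkage ------------------------------------------------------
    st = stage("linkage")
    gm = linkage.GenotypeMatrix.from_locus_set(loci)
    gm.ril_ids = kept.ril_ids
    min_support = int(config.get("linkage", "min_support", 30))
    min_support = min(min_support, max(2, int(0.7 * gm.n_rils)))
    kept_idx, skewed_idx, missing_idx = linkage.filter_markers(
        gm,
        max_missing_rils=config.get("linkage", "max_missing_rils", None),
        min_allele_ratio=float(config.get("linkage", "min_allele_ratio", 0.2)))
    gm_f = gm.subset(kept_idx)
    lmap, pairs = linkage.build_linkage_map(
        gm_f,
        r_max=float(config.get("linkage", "r_max", 0.2)),
        min_support=min_support,
        map_function=str(config.get("linkage", "map_function", "kosambi")),
        ril_correction=bool(config.get("linkage", "ril_correction", True)),
        ripple_window=int(config.get("linkage", "ripple_window", 5)))
    st["n_filtered_in"] = int(len(kept_idx))
    st["n_excluded_skewed"] = int(len(skewed_idx))
    st["n_excluded_missing"] = int(len(missing_idx))
    st["n_groups"] = len(lmap.groups)
    st["group_sizes"] = [int(len(g.loci)) for g in lmap.groups]
    st["bin_counts"] = [g.bins.counts() for g in lmap.groups]
    st["map_length_raw"] = lmap.total_length

    # --- curation -----------------------------------------------------
    st = stage("curation")
    cur = curation.curate_map(
        gm_f, lmap,
        cluster_min=int(config.get("curation", "cluster_min", 2)),
        min_support=min_support,
        ripple_window=int(config.get("linkage", "ripple_window", 5)))
    st["map_lengths"] = list(cur.lengths)
    st["double_recombinants"] = list(cur.double_recombinants)
    st["n_masked_het"] = cur.n_masked_het
    st["n_masked_dr"] = cur.n_masked_dr

    # rescue of skewed loci into gap regions, then final remap
    # (full original matrix is needed for cross pairs with skewed loci)
    lmap_final = cur.map_v2
    if len(skewed_idx):
        sub_idx = np.concatenate((kept_idx, skewed_idx))
        gm_all = gm.subset(sub_idx)
        gm_all.geno[:len(kept_idx)] = cur.gm_v2.geno
        pairs_all = linkage.pairwise_r(gm_all, low_support_floor=min_support)
        remapped_groups = []
        for g in lmap_final.groups:
            remapped_groups.append(g)
        lmap_resc, rescue_report = linkage.rescue_distorted(
            gm_all, pairs_all,
            linkage.LinkageMap(groups=remapped_groups,
                               map_function=lmap_final.map_function,
                               ril_correction=lmap_final.ril_correction),
            skewed=np.arange(len(kept_idx), len(sub_idx)),
            gap_threshold=float(config.get("linkage", "gap_threshold", 20.0)),
            r_max=float(config.get("linkage", "r_max", 0.2)),
            min_support=min_support,
            map_function=lmap_final.map_function,
            ril_correction=lmap_final.ril_correction)
        st["rescue"] = rescue_report.to_dict("records")
        gm_map, lmap_final = gm_all, lmap_resc
    else:
        gm_map = cur.gm_v2
    map_table = lmap_final.to_table(gm_map)
    if write_files:
        map_table.to_csv(out / "map.tsv", sep="\t", index=False,
                         float_format="%.4f")
        cur.report().to_csv(out / "curation_report.tsv", sep="\t",
                            index=False, float_format="%.2f")
        cur.het_regions.to_csv(out / "het_regions.tsv", sep="\t", index=False)

    # --- stats --------------------------------------------------------
    st = stage("stats")
    dist = mapstats.distortion_table(gm_map)
    st["distorted_frac_05"] = float(dist["significant_05"].mean())
    st["distorted_frac_01"] = float(dist["significant_01"].mean())
    interval_rows = []
    for g in cur.map_v2.groups:
        try:
            res = mapstats.poisson_interval_test(
                g.positions, interval=float(config.get("stats", "spacing",
                                                       5.0)))
        except ValueError:
            continue
        res["group"] = g.label
        interval_rows.append(res)
    st["poisson_interval"] = interval_rows
    xo = mapstats.crossover_counts(
        cur.gm_v2, cur.map_v2,
        spacing=float(config.get("stats", "spacing", 5.0)))
    per_ril = xo.groupby("ril")["crossovers"].sum()
    st["crossovers_mean"] = float(per_ril.mean())
    st["crossovers_min"] = int(per_ril.min())
    st["crossovers_max"] = int(per_ril.max())
    st["expected_residual_het_pct"] = mapstats.expected_residual_het(
        sim_cfg.n_generations)
    st["simulated_het_pct"] = 100.0 * truth.het_fraction()
    if write_files:
        dist.to_csv(out / "distortion.tsv", sep="\t", index=False,
                    float_format="%.4g")
        xo.to_csv(out / "crossovers.tsv", sep="\t", index=False)
        if interval_rows:
            pd.DataFrame(interval_rows).to_csv(
                out / "interval_test.tsv", sep="\t", index=False,
                float_format="%.4g")
        # LD in long format over ~evenly spaced representatives
        ld_rows = []
        codes_all = gm_map.loci["code"].to_numpy()
        grid = []
        miss_all = gm_map.missing_counts()
        for g in cur.map_v2.groups:
            grid.extend(mapstats._grid_markers(
                g.order, g.positions, miss_all, codes_all,
                float(config.get("stats", "ld_interval", 5.0))))
        grid = sorted(set(int(i) for i in grid))
        for ai in range(len(grid)):
            for bi in range(ai + 1, len(grid)):
                try:
                    v = mapstats.ld_r2(gm_map.geno[grid[ai]],
                                       gm_map.geno[grid[bi]])
                except ValueError:
                    continue
                ld_rows.append((codes_all[grid[ai]], codes_all[grid[bi]], v))
        pd.DataFrame(ld_rows, columns=["locus_i", "locus_j", "r2"]).to_csv(
            out / "ld.tsv", sep="\t", index=False, float_format="%.4f")
        # pairwise recombination among mapped representatives, per group
        pair_rows = []
        pairs_final = linkage.pairwise_r(gm_map) if gm_map.n_loci > 1 else None
        for g in cur.map_v2.groups:
            reps = g.order
            for ai in range(len(reps)):
                for bi in range(ai + 1, len(reps)):
                    pair_rows.append((
                        g.label, codes_all[reps[ai]], codes_all[reps[bi]],
                        int(pairs_final.n_informative[reps[ai], reps[bi]]),
                        int(pairs_final.n_recombinant[reps[ai], reps[bi]]),
                        float(pairs_final.r_hat[reps[ai], reps[bi]])))
        pd.DataFrame(pair_rows, columns=[
            "group", "locus_i", "locus_j", "n_informative",
            "n_recombinant", "r_hat"]).to_csv(
            out / "pairwise_r.tsv", sep="\t", index=False,
            float_format="%.4f")

    # --- export -------------------------------------------------------
    st = stage("export")
    genome = export.build_quasi_genome(
        map_table, gm_map.loci,
        bp_per_cm=int(config.get("export", "bp_per_cm", export.BP_PER_CM)),
        locus_length=int(config.get("export", "locus_length", 1000)),
        min_spacer=int(config.get("export", "min_spacer", export.MIN_SPACER)))
    st["n_features"] = int(len(genome.features))
    st["total_bp"] = int(sum(genome.group_lengths.values()))
    if write_files:
        paths = export.write_outputs(genome, out, map_table=map_table)
        st["files"] = {k: str(v) for k, v in paths.items()}

    report["elapsed_s"] = round(time.time() - t0, 2)
    if write_files:
        checks = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "report.json":
                checks[str(p.relative_to(out))] = _sha256(p)
        report["checksums"] = checks
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
    # stash in-memory results for library callers
    report["_objects"] = {
        "truth": truth, "data": data, "calls": calls, "ranges": kept,
        "loci": loci, "gm": gm, "gm_filtered": gm_f, "curation": cur,
        "map_final": lmap_final, "gm_map": gm_map, "map_table": map_table,
        "kept_idx": kept_idx, "skewed_idx": skewed_idx,
    }
    return report
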