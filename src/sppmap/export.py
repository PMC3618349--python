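"""Quasi-genome export: genetic map as FASTA pseudomolecules + GFF3.

For genome-browser display of a genetic map, mapped unigene placeholder
sequences are concatenated in genetic order per linkage group, separated
by runs of 'N' scaled so that 1 cM corresponds to ``bp_per_cm`` bases
(default 1,730,000, the published scaling of 1585 cM to a 2.7-Gb
genome).  Markers within a bin share a cM position and are ordered
deterministically by their four-letter code; a configurable minimum
spacer separates them.  For unigenes split into two consensus-haplotype
loci, both positions are displayed only when they fall on different
linkage groups or more than 5 cM apart; otherwise only the 5' locus is
shown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "QuasiGenome",
    "build_quasi_genome",
    "write_outputs",
    "recover_cm_gaps",
    "BP_PER_CM",
]

#: published genetic-to-physical scaling: 1 cM = 1730 kb
BP_PER_CM = 1_730_000

#: minimum 'N' spacer between markers at the same cM position
MIN_SPACER = 100

_FASTA_WIDTH = 80
_BASES = np.array(list("ACGT"))


def _placeholder_sequence(locus_id: int, length: int) -> str:
    """Deterministic pseudo-random placeholder sequence for one locus."""
    rng = np.random.default_rng(1_000_003 + int(locus_id))
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class QuasiGenome:
    """Feature coordinates of a quasi-genomic map representation.

    ``features`` has 1-based inclusive ``start``/``end`` per displayed
    locus; sequences are generated on demand when writing FASTA.
    """

    features: pd.DataFrame  # seqid, start, end, code, unigene_id, part, cm
    group_lengths: Dict[str, int]
    bp_per_cm: int = BP_PER_CM
    min_spacer: int = MIN_SPACER
    locus_length: int = 1000


def _displayed_loci(map_table: pd.DataFrame, loci: pd.DataFrame,
                    split_display_cm: float = 5.0) -> pd.DataFrame:
    """Apply the split-haplotype display rule to the mapped loci."""
    merged = map_table.merge(
        loci[["code", "locus_id", "part"]], on="code", how="left")
    drop = set()
    for uid, sub in merged.groupby("unigene_id"):
        if len(sub) < 2 or (sub["part"] == "whole").all():
            continue
        groups = sub["group"].unique()
        if len(groups) > 1:
            continue
        span = sub["position_cm"].max() - sub["position_cm"].min()
        if span > split_display_cm:
            continue
        # show only the 5' half (or the first by code)
        pref = sub.assign(_rank=(sub["part"] != "5'-half").astype(int))
        keep = pref.sort_values(["_rank", "code"]).index[0]
        drop.update(i for i in sub.index if i != keep)
    return merged.drop(index=sorted(drop)).reset_index(drop=True)


def build_quasi_genome(map_table: pd.DataFrame, loci: pd.DataFrame,
                       bp_per_cm: int = BP_PER_CM,
                       locus_length: int = 1000,
                       min_spacer: int = MIN_SPACER,
                       split_display_cm: float = 5.0) -> QuasiGenome:
    """Assign quasi-genomic coordinates to every displayed mapped locus.

    ``map_table`` is the ordered map (columns ``group, position_cm,
    code, unigene_id``, one row per displayed marker) and ``loci`` the
    locus table providing ``locus_id`` and ``part`` per code.  Markers
    sharing a cM position are ordered by code and separated by the
    minimum spacer.
    """
    shown = _displayed_loci(map_table, loci, split_display_cm)
    rows = []
    lengths: Dict[str, int] = {}
    for group, sub in shown.groupby("group", sort=True):
        sub = sub.sort_values(["position_cm", "code"]).reset_index(drop=True)
        cursor = 0  # bases consumed so far
        prev_cm = 0.0
        for _, rec in sub.iterrows():
            gap_cm = float(rec["position_cm"]) - prev_cm
            spacer = max(int(round(gap_cm * bp_per_cm)), min_spacer)
            start = cursor + spacer + 1
            end = start + locus_length - 1
            rows.append({
                "seqid": group, "start": start, "end": end,
                "code": rec["code"], "unigene_id": int(rec["unigene_id"]),
                "part": rec.get("part", "whole"),
                "cm": float(rec["position_cm"]),
                "locus_id": int(rec["locus_id"]),
            })
            cursor = end
            prev_cm = float(rec["position_cm"])
        lengths[group] = cursor + min_spacer  # trailing pad
    features = pd.DataFrame(rows, columns=["seqid", "start", "end", "code",
                                           "unigene_id", "part", "cm",
                                           "locus_id"])
    return QuasiGenome(features=features, group_lengths=lengths,
                       bp_per_cm=bp_per_cm, min_spacer=min_spacer,
                       locus_length=locus_length)


def recover_cm_gaps(genome: QuasiGenome, seqid: str) -> np.ndarray:
    """cM gaps between consecutive displayed loci, inverted from coordinates.

    Exact up to the 1-bp rounding of the spacer, except where the gap
    hit the minimum-spacer floor.
    """
    sub = genome.features[genome.features["seqid"] == seqid]
    sub = sub.sort_values("start")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    spacers = starts[1:] - ends[:-1] - 1
    return spacers / genome.bp_per_cm


def write_outputs(genome: QuasiGenome, outdir,
                  map_table: Optional[pd.DataFrame] = None) -> Dict[str, Path]:
    """Write quasi-chromosome FASTA, GFF3 features and the map table.

    FASTA is wrapped at 80 columns; GFF3 uses 1-based inclusive
    coordinates, seqid = linkage group, strand '.', and attributes
    carrying the four-letter code, unigene id and cM position.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = out / "quasi_genome.fasta"
    with open(fasta, "w") as fh:
        for seqid in sorted(genome.group_lengths):
            fh.write(f">{seqid}\n")
            sub = genome.features[genome.features["seqid"] == seqid]
            sub = sub.sort_values("start")
            buf: List[str] = []
            pos = 0  # bases emitted
            for _, rec in sub.iterrows():
                buf.append("N" * (int(rec["start"]) - 1 - pos))
                buf.append(_placeholder_sequence(int(rec["locus_id"]),
                                                 genome.locus_length))
                pos = int(rec["end"])
            buf.append("N" * (genome.group_lengths[seqid] - pos))
            seq = "".join(buf)
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i:i + _FASTA_WIDTH])
                fh.write("\n")
    paths["fasta"] = fasta

    gff = out / "quasi_genome.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in sorted(genome.group_lengths):
            fh.write(f"##sequence-region {seqid} 1 "
                     f"{genome.group_lengths[seqid]}\n")
        feats = genome.features.sort_values(["seqid", "start"])
        for _, rec in feats.iterrows():
            attrs = (f"ID={rec['code']};Name={rec['code']};"
                     f"unigene_id={rec['unigene_id']};part={rec['part']};"
                     f"cM={rec['cm']:.4f}")
            fh.write("\t".join([
                str(rec["seqid"]), "sppmap", "gene",
                str(int(rec["start"])), str(int(rec["end"])),
                ".", ".", ".", attrs]) + "\n")
    paths["gff3"] = gff

    if map_table is not None:
        mt = out / "map.tsv"
        map_table.to_csv(mt, sep="\t", index=False, float_format="%.4f")
        paths["map"] = mt
    return paths
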