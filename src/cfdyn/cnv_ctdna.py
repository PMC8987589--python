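"""Copy-number gain calling and ctDNA accounting.

Segments whose total copy number estimate exceeds a strict threshold
(> 8 by default) are called gains; gains are annotated with the cancer
genes whose intervals they overlap, compared between the baseline and
resistance time points, and the FACETS-style tumor-fraction estimate is
converted to an absolute ctDNA amount (fraction x total cfDNA, ng).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .data_model_io import Segment, Timepoint

GAIN_THRESHOLD_DEFAULT = 8.0


@dataclass
class GeneInterval:
    """Half-open 0-based interval of one cancer gene."""

    gene: str
    chrom: str
    start: int
    end: int


@dataclass
class CnvCall:
    segment: Segment
    genes: list[str]
    gain: bool
    timepoint: Timepoint | None = None


@dataclass
class CtdnaEstimate:
    sample_id: str
    fraction: float
    amount: float | None  # ng; None when total cfDNA unknown


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read a BED file (chrom, start, end, gene) of cancer-gene intervals."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path} line {i}: expected 4 BED columns")
            out.append(GeneInterval(gene=parts[3], chrom=parts[0],
                                    start=int(parts[1]), end=int(parts[2])))
    return out


def _overlaps(seg: Segment, gi: GeneInterval) -> bool:
    return seg.chrom == gi.chrom and seg.start < gi.end and gi.start < seg.end


def call_gains(segments: list[Segment],
               gene_intervals: list[GeneInterval],
               gain_threshold: float = GAIN_THRESHOLD_DEFAULT,
               timepoint: Timepoint | None = None) -> list[CnvCall]:
    """One call per segment: gain iff tcn strictly exceeds the threshold;
    genes are all cancer genes whose interval overlaps the segment."""
    calls = []
    for seg in segments:
        genes = sorted(gi.gene for gi in gene_intervals if _overlaps(seg, gi))
        calls.append(CnvCall(segment=seg, genes=genes,
                             gain=seg.tcn > gain_threshold,
                             timepoint=timepoint))
    return calls


def gained_genes(calls: list[CnvCall]) -> set[str]:
    return {g for c in calls if c.gain for g in c.genes}


def gene_mean_tcn(calls: list[CnvCall]) -> dict[str, float]:
    """Mean tcn across the segments overlapping each gene (length-weighted
    would require sub-segment bookkeeping; unweighted mean is reported)."""
    acc: dict[str, list[float]] = {}
    for c in calls:
        for g in c.genes:
            acc.setdefault(g, []).append(c.segment.tcn)
    return {g: sum(v) / len(v) for g, v in acc.items()}


def compare_cnv_timepoints(base_calls: list[CnvCall],
                           res_calls: list[CnvCall]) -> pd.DataFrame:
    """Per-gene gain status across the two time points.

    One row per gene gained at either time point, with status in
    {base_only, res_only, both}; genes gained nowhere do not appear.
    """
    base_g, res_g = gained_genes(base_calls), gained_genes(res_calls)
    rows = []
    for gene in sorted(base_g | res_g):
        status = ("both" if gene in base_g and gene in res_g
                  else "base_only" if gene in base_g else "res_only")
        rows.append({"gene": gene, "status": status})
    return pd.DataFrame(rows, columns=["gene", "status"])


def ctdna_amount(fraction: float, cfdna_total: float) -> float:
    """ctDNA amount in ng: tumor fraction x total cfDNA."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"tumor fraction {fraction} outside [0, 1]")
    if cfdna_total < 0:
        raise ValueError("cfDNA amount must be >= 0")
    return fraction * cfdna_total


def estimate_ctdna(sample_id: str, fraction: float,
                   cfdna_total: float | None) -> CtdnaEstimate:
    amount = None if cfdna_total is None else ctdna_amount(fraction, cfdna_total)
    return CtdnaEstimate(sample_id=sample_id, fraction=fraction, amount=amount)


def write_gains_table(calls: list[CnvCall], sample_id: str, path) -> None:
    rows = [{"sample": sample_id, "chrom": c.segment.chrom,
             "start": c.segment.start, "end": c.segment.end,
             "tcn": c.segment.tcn, "genes": ";".join(c.genes),
             "gain": int(c.gain)} for c in calls]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "tcn",
                                "genes", "gain"]).to_csv(path, sep="\t",
                                                         index=False)
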