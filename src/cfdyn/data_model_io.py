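"""Domain types and on-disk formats for the paired-cfDNA pipeline.

Every downstream stage (filtering, VAF dynamics, recurrence, signatures,
copy number, statistics) consumes the containers defined here.  I/O is
lossless: readers never drop records silently, and anything malformed
raises an error naming the offending record or line.

Coordinate conventions
----------------------
Variants follow the VCF convention: 1-based, inclusive positions.
Copy-number segment tables are assumed 1-based inclusive on disk (the
convention of allele-specific copy-number callers) and are normalised to
0-based half-open ``[start, end)`` intervals on read, so that interval
arithmetic downstream has a single convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from cyvcf2 import VCF

ACCEPTED_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


class Region(enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    OTHER = "other"


class Effect(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    NONFRAMESHIFT_SUBSTITUTION = "nonframeshift_substitution"
    SPLICE = "splice"
    UTR = "utr"
    OTHER = "other"


class Timepoint(enum.Enum):
    BASELINE = "baseline"
    RESISTANCE = "resistance"


class CancerType(enum.Enum):
    LUNG = "lung"
    COLORECTAL = "colorectal"


class Treatment(enum.Enum):
    CYTOTOXIC = "cytotoxic"
    EGFR_TKI = "egfr_tki"
    CETUXIMAB = "cetuximab"


# ANNOVAR-style effect strings -> internal enum.  Unknown strings map to OTHER.
_EFFECT_MAP = {
    "synonymous": Effect.SYNONYMOUS,
    "synonymous snv": Effect.SYNONYMOUS,
    "synonymous_snv": Effect.SYNONYMOUS,
    "nonsynonymous": Effect.MISSENSE,
    "nonsynonymous snv": Effect.MISSENSE,
    "nonsynonymous_snv": Effect.MISSENSE,
    "missense": Effect.MISSENSE,
    "stopgain": Effect.NONSENSE,
    "stoploss": Effect.NONSENSE,
    "nonsense": Effect.NONSENSE,
    "frameshift": Effect.FRAMESHIFT,
    "frameshift insertion": Effect.FRAMESHIFT,
    "frameshift_insertion": Effect.FRAMESHIFT,
    "frameshift deletion": Effect.FRAMESHIFT,
    "frameshift_deletion": Effect.FRAMESHIFT,
    "nonframeshift substitution": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "nonframeshift_substitution": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "nonframeshift insertion": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "nonframeshift_insertion": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "nonframeshift deletion": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "nonframeshift_deletion": Effect.NONFRAMESHIFT_SUBSTITUTION,
    "splicing": Effect.SPLICE,
    "splice": Effect.SPLICE,
    "utr": Effect.UTR,
    "utr3": Effect.UTR,
    "utr5": Effect.UTR,
}

_REGION_MAP = {
    "exonic": Region.EXONIC,
    "splicing": Region.SPLICING,
    "exonic;splicing": Region.EXONIC,
}


class FormatError(ValueError):
    """Raised for malformed on-disk inputs; message names the record/line."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic coordinates + alleles of one variant (VCF convention, 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.chrom not in ACCEPTED_CHROMS:
            raise ValueError(f"unexpected contig {self.chrom!r}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class VariantCall:
    """One somatic variant observed in one sample.

    ``vaf``/``depth``/``alt_reads``/``qual`` come from the caller; the
    annotation fields (gene, region, effect, population frequency, COSMIC id)
    are filled by :func:`annotate_calls` and default to "unknown" values.
    """

    key: VariantKey
    vaf: float
    depth: int
    alt_reads: int
    qual: float
    gene: str = ""
    region: Region = Region.OTHER
    effect: Effect = Effect.OTHER
    protein_change: str = ""
    pop_af_max: float = 0.0
    cosmic_id: str = ""
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} > depth {self.depth} at "
                f"{self.key.chrom}:{self.key.pos}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")


@dataclass
class SampleCallset:
    sample_id: str
    patient_id: str
    timepoint: Timepoint
    calls: list[VariantCall]
    tumor_fraction: float | None = None
    cfdna_amount: float | None = None

    def __post_init__(self) -> None:
        keys = [c.key for c in self.calls]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant keys in sample {self.sample_id}")


@dataclass
class PatientRecord:
    patient_id: str
    cancer_type: CancerType
    treatment: Treatment
    survival_time: float
    event: int
    residual_tumor_size: float | None = None  # None = non-measurable (< 5 mm)

    def __post_init__(self) -> None:
        if self.survival_time < 0:
            raise ValueError("survival_time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class PatientPaths:
    baseline_vcf: str
    resistance_vcf: str
    baseline_annotation: str
    resistance_annotation: str
    baseline_segments: str
    resistance_segments: str
    contexts: str = ""
    baseline_tumor_fraction: float | None = None
    resistance_tumor_fraction: float | None = None
    baseline_cfdna_amount: float | None = None
    resistance_cfdna_amount: float | None = None


@dataclass
class CohortManifest:
    patients: list[PatientRecord]
    pairs: dict[str, PatientPaths]

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        missing = ids - set(self.pairs)
        if missing:
            raise ValueError(f"patients without sample pairs: {sorted(missing)}")


@dataclass
class Segment:
    """Copy-number segment, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    tcn: float
    lcn: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.tcn < 0:
            raise ValueError("tcn must be >= 0")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_calls(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read per-sample somatic calls from a VCF (v4.2+).

    Requires FORMAT fields DP and AD (ref, alt...); uses AF when present,
    otherwise vaf = alt_reads / depth.  Multi-allelic records are decomposed
    into one call per ALT allele.  Annotation fields are left unset.
    """
    vcf = VCF(str(path))
    if sample_id not in vcf.samples:
        raise FormatError(f"sample {sample_id!r} not in VCF {path}")
    si = vcf.samples.index(sample_id)

    calls: list[VariantCall] = []
    for rec in vcf:
        where = f"{rec.CHROM}:{rec.POS} {rec.REF}>{','.join(rec.ALT)}"
        try:
            dp = rec.format("DP")
            ad = rec.format("AD")
        except KeyError:
            dp = ad = None
        if dp is None or ad is None:
            raise FormatError(f"record {where}: missing DP or AD FORMAT field")
        depth = int(dp[si][0])
        ad_row = [int(x) for x in ad[si]]
        if len(ad_row) != len(rec.ALT) + 1:
            raise FormatError(f"record {where}: AD has {len(ad_row)} values for "
                              f"{len(rec.ALT)} alt allele(s)")
        af = None
        try:
            af_arr = rec.format("AF")
            if af_arr is not None:
                af = [float(x) for x in af_arr[si]]
        except KeyError:
            pass
        qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
        for j, alt in enumerate(rec.ALT):
            alt_reads = ad_row[j + 1]
            if af is not None and j < len(af):
                vaf = af[j]
            else:
                vaf = alt_reads / depth if depth > 0 else 0.0
            calls.append(VariantCall(
                key=VariantKey(rec.CHROM, rec.POS, rec.REF, alt),
                vaf=vaf, depth=depth, alt_reads=alt_reads, qual=qual,
            ))
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf_calls(calls: Iterable[VariantCall], path: str | Path,
                    sample_id: str) -> None:
    """Write calls as a minimal single-sample VCF (GT:DP:AD:AF).

    Inverse of :func:`read_vcf_calls` for (key, depth, alt_reads, qual);
    multi-allelic sites are written as separate bi-allelic records.
    """
    calls = sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.key.alt))
    contigs = "".join(f"##contig=<ID={c}>\n"
                      for c in sorted({c.key.chrom for c in calls},
                                      key=_chrom_sort_key))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample_id))
        for c in calls:
            ref_reads = c.depth - c.alt_reads
            fh.write(
                f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t"
                f"{c.qual:g}\tPASS\t.\tGT:DP:AD:AF\t"
                f"0/1:{c.depth}:{ref_reads},{c.alt_reads}:{c.vaf:.6f}\n"
            )


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):02d}") if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_ANN_REQUIRED = ["chrom", "pos", "ref", "alt", "gene", "region", "effect",
                 "protein_change", "af_1000g", "af_panel", "cosmic_id"]


@dataclass
class Annotation:
    gene: str
    region: Region
    effect: Effect
    protein_change: str
    pop_af_max: float
    cosmic_id: str


def read_annotation_table(path: str | Path) -> dict[VariantKey, Annotation]:
    """Read a tab-separated ANNOVAR-like annotation table.

    ``pop_af_max`` is the max of the available population frequencies
    (two panels; missing values encoded "."), 0 when all are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table {path}: missing columns {missing}")

    out: dict[VariantKey, Annotation] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in out:
            raise FormatError(f"annotation table line {i}: duplicate key "
                              f"{key.chrom}:{key.pos} {key.ref}>{key.alt}")
        freqs = [float(v) for v in (row.af_1000g, row.af_panel)
                 if v not in (".", "")]
        out[key] = Annotation(
            gene=row.gene,
            region=_REGION_MAP.get(row.region.strip().lower(), Region.OTHER),
            effect=_EFFECT_MAP.get(row.effect.strip().lower(), Effect.OTHER),
            protein_change="" if row.protein_change == "." else row.protein_change,
            pop_af_max=max(freqs) if freqs else 0.0,
            cosmic_id="" if row.cosmic_id == "." else row.cosmic_id,
        )
    return out


def annotate_calls(calls: list[VariantCall],
                   ann: Mapping[VariantKey, Annotation]) -> list[VariantCall]:
    """Fill annotation fields on calls with a matching key.

    Calls without a match keep default fields and stay flagged
    ``annotated=False``; output length always equals input length.
    """
    out = []
    for c in calls:
        a = ann.get(c.key)
        if a is None:
            out.append(replace(c, annotated=False))
        else:
            out.append(replace(
                c, gene=a.gene, region=a.region, effect=a.effect,
                protein_change=a.protein_change, pop_af_max=a.pop_af_max,
                cosmic_id=a.cosmic_id, annotated=True,
            ))
    return out


def write_annotation_table(rows: Mapping[VariantKey, Annotation],
                           path: str | Path) -> None:
    recs = []
    for key in sorted(rows, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.alt)):
        a = rows[key]
        recs.append({
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
            "gene": a.gene, "region": a.region.value, "effect": a.effect.value,
            "protein_change": a.protein_change or ".",
            "af_1000g": f"{a.pop_af_max:g}" if a.pop_af_max > 0 else ".",
            "af_panel": ".",
            "cosmic_id": a.cosmic_id or ".",
        })
    pd.DataFrame(recs, columns=_ANN_REQUIRED).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[Segment]:
    """Read a tab-separated copy-number segment table (chrom, start, end,
    tcn.em, lcn.em).

    On-disk coordinates are 1-based inclusive and normalised to 0-based
    half-open here.  Segments are returned sorted by (chrom, start);
    overlapping segments on one chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "start", "end", "tcn.em"):
        if col not in df.columns:
            raise FormatError(f"segment table {path}: missing column {col!r}")
    df = df.rename(columns={"tcn.em": "tcn_em", "lcn.em": "lcn_em"})
    segs: list[Segment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        start1, end1 = int(row.start), int(getattr(row, "end"))
        if end1 < start1:
            raise FormatError(f"segment table line {i}: end {end1} < start {start1}")
        lcn_raw = getattr(row, "lcn_em", ".")
        segs.append(Segment(
            chrom=str(row.chrom), start=start1 - 1, end=end1,
            tcn=float(getattr(row, "tcn_em")),
            lcn=None if lcn_raw in (".", "") else float(lcn_raw),
        ))
    segs.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise FormatError(
                f"segment table {path}: overlapping segments "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}")
    return segs


def write_segments(segs: Iterable[Segment], path: str | Path) -> None:
    """Write segments back to the 1-based inclusive on-disk convention."""
    recs = [{"chrom": s.chrom, "start": s.start + 1, "end": s.end,
             "tcn.em": f"{s.tcn:g}",
             "lcn.em": "." if s.lcn is None else f"{s.lcn:g}"}
            for s in segs]
    pd.DataFrame(recs, columns=["chrom", "start", "end", "tcn.em", "lcn.em"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene x patient dynamics matrix (oncoprint export)
# ---------------------------------------------------------------------------

def write_gene_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x patient matrix of dynamics-class codes as TSV.

    Rows are genes, columns patients; round-trips losslessly through
    :func:`read_gene_matrix`.
    """
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_gene_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", dtype=str,
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# Cohort manifest (YAML)
# ---------------------------------------------------------------------------

def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    doc = {"patients": [], "pairs": {}}
    for p in manifest.patients:
        doc["patients"].append({
            "patient_id": p.patient_id,
            "cancer_type": p.cancer_type.value,
            "treatment": p.treatment.value,
            "survival_time": p.survival_time,
            "event": p.event,
            "residual_tumor_size": p.residual_tumor_size,
        })
    for pid, pp in manifest.pairs.items():
        doc["pairs"][pid] = {k: v for k, v in vars(pp).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path: str | Path) -> CohortManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    patients = [PatientRecord(
        patient_id=d["patient_id"],
        cancer_type=CancerType(d["cancer_type"]),
        treatment=Treatment(d["treatment"]),
        survival_time=float(d["survival_time"]),
        event=int(d["event"]),
        residual_tumor_size=d.get("residual_tumor_size"),
    ) for d in doc["patients"]]
    pairs = {pid: PatientPaths(**pp) for pid, pp in doc["pairs"].items()}
    return CohortManifest(patients=patients, pairs=pairs)


def load_sample(vcf_path: str | Path, ann_path: str | Path, sample_id: str,
                patient_id: str, timepoint: Timepoint,
                tumor_fraction: float | None = None,
                cfdna_amount: float | None = None) -> SampleCallset:
    """Read and annotate one sample's calls into a :class:`SampleCallset`."""
    calls = read_vcf_calls(vcf_path, sample_id)
    ann = read_annotation_table(ann_path)
    return SampleCallset(
        sample_id=sample_id, patient_id=patient_id, timepoint=timepoint,
        calls=annotate_calls(calls, ann),
        tumor_fraction=tumor_fraction, cfdna_amount=cfdna_amount,
    )
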