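"""Per-patient VAF dynamics between baseline and acquired-resistance draws.

Each variant present in either time point's filtered call set gets one
dynamics class:

* ``RES_ONLY``  — undetected at baseline, detected at resistance
* ``VAF_UP``    — detected at both, VAF increased by more than 5 points
* ``BASE_ONLY`` — detected at baseline, undetected at resistance
* ``VAF_DOWN``  — detected at both, VAF decreased by more than 5 points
* ``STABLE``    — otherwise

"Detected" means VAF at or above the assay detection floor (1% by
default); a variant absent from a time point's passing set has VAF 0
there.  Gene-level labels take the variant with the largest absolute
VAF change, with ties broken by class precedence then genomic order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .data_model_io import SampleCallset, VariantKey


class DynamicsClass(enum.Enum):
    RES_ONLY = "res_only"
    VAF_UP = "vaf_up"
    BASE_ONLY = "base_only"
    VAF_DOWN = "vaf_down"
    STABLE = "stable"

    @property
    def resistance_direction(self) -> bool:
        return self in (DynamicsClass.RES_ONLY, DynamicsClass.VAF_UP)

    @property
    def baseline_direction(self) -> bool:
        return self in (DynamicsClass.BASE_ONLY, DynamicsClass.VAF_DOWN)


# tie-break precedence for gene-level aggregation (highest first)
_PRECEDENCE = {
    DynamicsClass.RES_ONLY: 0,
    DynamicsClass.VAF_UP: 1,
    DynamicsClass.BASE_ONLY: 2,
    DynamicsClass.VAF_DOWN: 3,
    DynamicsClass.STABLE: 4,
}


@dataclass
class VariantDynamics:
    patient_id: str
    key: VariantKey
    gene: str
    vaf_base: float
    vaf_res: float
    cls: DynamicsClass
    protein_change: str = ""

    @property
    def delta(self) -> float:
        return self.vaf_res - self.vaf_base


@dataclass
class GeneDynamics:
    patient_id: str
    gene: str
    cls: DynamicsClass
    representative: VariantKey
    max_abs_delta: float


def classify_variant(vaf_base: float, vaf_res: float,
                     detect_floor: float = 0.01,
                     delta_threshold: float = 0.05) -> DynamicsClass:
    """Classify one variant's VAF change between the two time points.

    Presence at a time point means VAF >= ``detect_floor``; among variants
    present at both, an absolute VAF change exceeding ``delta_threshold``
    (5 percentage points) is called up/down, anything smaller is stable.
    """
    for v in (vaf_base, vaf_res):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"VAF {v} outside [0, 1]")
    if vaf_base < detect_floor <= vaf_res:
        return DynamicsClass.RES_ONLY
    if vaf_res < detect_floor <= vaf_base:
        return DynamicsClass.BASE_ONLY
    delta = vaf_res - vaf_base
    if delta > delta_threshold:
        return DynamicsClass.VAF_UP
    if delta < -delta_threshold:
        return DynamicsClass.VAF_DOWN
    return DynamicsClass.STABLE


def pair_variants(base: SampleCallset, res: SampleCallset,
                  detect_floor: float = 0.01,
                  delta_threshold: float = 0.05) -> list[VariantDynamics]:
    """Union the two filtered call sets and classify each variant.

    A variant absent from one time point's passing set contributes VAF 0
    there.  Both call sets must belong to the same patient.
    """
    if base.patient_id != res.patient_id:
        raise ValueError(f"patient mismatch: {base.patient_id!r} vs "
                         f"{res.patient_id!r}")
    base_by_key = {c.key: c for c in base.calls}
    res_by_key = {c.key: c for c in res.calls}
    out: list[VariantDynamics] = []
    for key in sorted(set(base_by_key) | set(res_by_key)):
        cb, cr = base_by_key.get(key), res_by_key.get(key)
        vb = cb.vaf if cb is not None else 0.0
        vr = cr.vaf if cr is not None else 0.0
        src = cr or cb
        out.append(VariantDynamics(
            patient_id=base.patient_id, key=key, gene=src.gene,
            vaf_base=vb, vaf_res=vr,
            cls=classify_variant(vb, vr, detect_floor, delta_threshold),
            protein_change=src.protein_change,
        ))
    return out


def gene_dynamics(vds: list[VariantDynamics]) -> list[GeneDynamics]:
    """Collapse variant dynamics to one class per gene.

    The representative variant is the one with the largest |delta|; ties
    break by class precedence (RES_ONLY > VAF_UP > BASE_ONLY > VAF_DOWN >
    STABLE), then by genomic order.
    """
    if not vds:
        return []
    patient_ids = {v.patient_id for v in vds}
    if len(patient_ids) > 1:
        raise ValueError(f"records from multiple patients: {sorted(patient_ids)}")
    by_gene: dict[str, list[VariantDynamics]] = {}
    for v in vds:
        by_gene.setdefault(v.gene, []).append(v)
    out = []
    for gene in sorted(by_gene):
        rep = min(by_gene[gene],
                  key=lambda v: (-abs(v.delta), _PRECEDENCE[v.cls], v.key))
        out.append(GeneDynamics(
            patient_id=rep.patient_id, gene=gene, cls=rep.cls,
            representative=rep.key, max_abs_delta=abs(rep.delta),
        ))
    return out


def write_dynamics_table(vds: list[VariantDynamics], path,
                         tumor_fraction_base: float | None = None,
                         tumor_fraction_res: float | None = None) -> None:
    """Per-patient dynamics TSV; optionally adds tumor-fraction-normalised
    deltas as a report-only column (raw VAFs drive the classification)."""
    with_tf = tumor_fraction_base and tumor_fraction_res
    with open(path, "w") as fh:
        cols = ["patient", "gene", "chrom", "pos", "ref", "alt",
                "vaf_base", "vaf_res", "delta", "class"]
        if with_tf:
            cols.append("delta_tf_normalized")
        fh.write("\t".join(cols) + "\n")
        for v in vds:
            row = [v.patient_id, v.gene, v.key.chrom, str(v.key.pos),
                   v.key.ref, v.key.alt, f"{v.vaf_base:.6f}",
                   f"{v.vaf_res:.6f}", f"{v.delta:+.6f}", v.cls.value]
            if with_tf:
                row.append(f"{v.vaf_res / tumor_fraction_res - v.vaf_base / tumor_fraction_base:+.6f}")
            fh.write("\t".join(row) + "\n")
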