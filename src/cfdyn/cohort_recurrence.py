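"""Cross-patient recurrence selection and oncoprint matrix construction.

A gene is resistance-associated when its dynamics class is RES_ONLY or
VAF_UP in at least ``min_patients`` patients (two by default, matching
the convention that genes recurrently emerging or rising at acquired
resistance in two or more patients are candidates); baseline-associated
genes use BASE_ONLY/VAF_DOWN symmetrically.  STABLE never counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .data_model_io import PatientRecord, Treatment
from .paired_dynamics import DynamicsClass, GeneDynamics

NO_ALTERATION = "none"


class Direction(enum.Enum):
    RESISTANCE = "resistance"
    BASELINE = "baseline"
    BOTH = "both"


@dataclass
class CohortGeneResult:
    gene: str
    n_res_patients: int
    n_base_patients: int
    per_treatment: dict[Treatment, int]
    selected: bool


def aggregate_cohort(gds: list[GeneDynamics], patients: list[PatientRecord],
                     min_patients: int = 2,
                     direction: Direction = Direction.RESISTANCE,
                     ) -> list[CohortGeneResult]:
    """Count, per gene, the patients altered in each direction and select
    genes meeting the recurrence threshold.

    Results are sorted by descending direction-relevant count, then gene
    name.  Each patient counts at most once per gene.
    """
    by_id = {p.patient_id: p for p in patients}
    unknown = {g.patient_id for g in gds} - set(by_id)
    if unknown:
        raise ValueError(f"gene dynamics reference unknown patients: "
                         f"{sorted(unknown)}")
    seen: set[tuple[str, str]] = set()
    res_count: dict[str, set[str]] = {}
    base_count: dict[str, set[str]] = {}
    treat_count: dict[str, dict[Treatment, int]] = {}
    for g in gds:
        if (g.patient_id, g.gene) in seen:
            raise ValueError(f"duplicate gene dynamics for "
                             f"({g.patient_id}, {g.gene})")
        seen.add((g.patient_id, g.gene))
        if g.cls is DynamicsClass.STABLE:
            continue
        if g.cls.resistance_direction:
            res_count.setdefault(g.gene, set()).add(g.patient_id)
        else:
            base_count.setdefault(g.gene, set()).add(g.patient_id)
        tr = by_id[g.patient_id].treatment
        treat_count.setdefault(g.gene, {})
        treat_count[g.gene][tr] = treat_count[g.gene].get(tr, 0) + 1

    def relevant(n_res: int, n_base: int) -> int:
        if direction is Direction.RESISTANCE:
            return n_res
        if direction is Direction.BASELINE:
            return n_base
        return max(n_res, n_base)

    out = []
    for gene in set(res_count) | set(base_count):
        n_res = len(res_count.get(gene, set()))
        n_base = len(base_count.get(gene, set()))
        out.append(CohortGeneResult(
            gene=gene, n_res_patients=n_res, n_base_patients=n_base,
            per_treatment=treat_count.get(gene, {}),
            selected=relevant(n_res, n_base) >= min_patients,
        ))
    out.sort(key=lambda r: (-relevant(r.n_res_patients, r.n_base_patients),
                            r.gene))
    return out


def build_oncoprint(gds: list[GeneDynamics], results: list[CohortGeneResult],
                    patients: list[PatientRecord]) -> pd.DataFrame:
    """Gene x patient matrix of dynamics-class codes for selected genes.

    Columns are ordered by treatment group then patient id; rows by
    descending resistance-patient count then gene name (a deterministic
    stand-in for presentational clustering).  Cells without an alteration
    hold the no-alteration code.
    """
    selected = [r for r in results if r.selected]
    row_order = [r.gene for r in sorted(
        selected, key=lambda r: (-r.n_res_patients, r.gene))]
    col_order = [p.patient_id for p in sorted(
        patients, key=lambda p: (p.treatment.value, p.patient_id))]
    mat = pd.DataFrame(NO_ALTERATION, index=pd.Index(row_order, name="gene"),
                       columns=col_order, dtype=object)
    selected_set = set(row_order)
    for g in gds:
        if g.gene in selected_set and g.cls is not DynamicsClass.STABLE:
            mat.loc[g.gene, g.patient_id] = g.cls.value
    return mat


def hotspot_table(vds_by_patient: dict[str, list], min_patients: int = 2,
                  ) -> pd.DataFrame:
    """Identical-protein-change recurrence (supplementary hotspot report).

    Counts, per (gene, protein_change), the number of patients carrying a
    resistance-direction variant with that exact protein change.
    """
    counts: dict[tuple[str, str], set[str]] = {}
    for pid, vds in vds_by_patient.items():
        for v in vds:
            pc = getattr(v, "protein_change", "") or ""
            if not pc or not v.cls.resistance_direction:
                continue
            counts.setdefault((v.gene, pc), set()).add(pid)
    rows = [{"gene": g, "protein_change": pc, "n_patients": len(pids)}
            for (g, pc), pids in counts.items() if len(pids) >= min_patients]
    return pd.DataFrame(rows, columns=["gene", "protein_change", "n_patients"]
                        ).sort_values(["n_patients", "gene"],
                                      ascending=[False, True]
                                      ).reset_index(drop=True)


def write_cohort_results(results: list[CohortGeneResult], path) -> None:
    rows = []
    for r in results:
        row = {"gene": r.gene, "n_res_patients": r.n_res_patients,
               "n_base_patients": r.n_base_patients,
               "selected": int(r.selected)}
        for t in Treatment:
            row[f"n_{t.value}"] = r.per_treatment.get(t, 0)
        rows.append(row)
    cols = ["gene", "n_res_patients", "n_base_patients",
            *[f"n_{t.value}" for t in Treatment], "selected"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
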