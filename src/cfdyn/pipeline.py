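"""End-to-end driver: cohort directory in, result tables out.

Thin orchestration over the stage modules — load and filter each
patient's paired call sets, classify VAF dynamics, aggregate recurrence,
refit signatures on the resistance samples, call copy-number gains, and
compute the cohort statistics.  All outputs are deterministic functions
of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cnv_ctdna, cohort_stats
from .cohort_recurrence import (
    Direction, aggregate_cohort, build_oncoprint, hotspot_table,
    write_cohort_results,
)
from .data_model_io import (
    CohortManifest, Timepoint, load_sample, read_manifest, read_segments,
    write_gene_matrix,
)
from .paired_dynamics import gene_dynamics, pair_variants
from .signature_refit import (
    SignatureMatrix, build_spectrum, refit_exposures, write_exposures,
)
from .synthetic_cohort import read_contexts
from .variant_filter import FilterConfig, filter_sample


@dataclass
class PipelineResult:
    manifest: CohortManifest
    gene_results: list
    oncoprint: pd.DataFrame
    dynamics: dict[str, list]            # patient -> VariantDynamics
    gene_dynamics: list
    exposures: dict[str, object]
    cnv_compare: dict[str, pd.DataFrame]
    stats: dict[str, object]
    audits: dict[str, object] = field(default_factory=dict)


def run_pipeline(input_dir: str | Path, output_dir: str | Path | None = None,
                 filter_config: FilterConfig | None = None,
                 min_patients: int = 2,
                 direction: Direction = Direction.RESISTANCE,
                 delta_threshold: float = 0.05,
                 detect_floor: float = 0.01,
                 signature_matrix: SignatureMatrix | None = None,
                 gene_intervals=None) -> PipelineResult:
    """Run the full paired-cohort analysis on a simulated or assembled
    cohort directory containing ``manifest.yaml`` and the per-sample files
    it references."""
    input_dir = Path(input_dir)
    manifest = read_manifest(input_dir / "manifest.yaml")
    filter_config = filter_config or FilterConfig()
    gene_intervals = gene_intervals or []

    dynamics, all_gds, audits, exposures, cnv_compare = {}, [], {}, {}, {}
    for patient in manifest.patients:
        pid = patient.patient_id
        paths = manifest.pairs[pid]
        base = load_sample(paths.baseline_vcf, paths.baseline_annotation,
                           f"{pid}_base", pid, Timepoint.BASELINE,
                           paths.baseline_tumor_fraction,
                           paths.baseline_cfdna_amount)
        res = load_sample(paths.resistance_vcf, paths.resistance_annotation,
                          f"{pid}_res", pid, Timepoint.RESISTANCE,
                          paths.resistance_tumor_fraction,
                          paths.resistance_cfdna_amount)
        base_f, audit_b = filter_sample(base, filter_config)
        res_f, audit_r = filter_sample(res, filter_config)
        audits[f"{pid}_base"], audits[f"{pid}_res"] = audit_b, audit_r

        vds = pair_variants(base_f, res_f, detect_floor, delta_threshold)
        dynamics[pid] = vds
        all_gds.extend(gene_dynamics(vds))

        if signature_matrix is not None and paths.contexts and res_f.calls:
            contexts = read_contexts(paths.contexts)
            spec = build_spectrum(res_f.calls, contexts)
            if spec.total > 0:
                exposures[f"{pid}_res"] = refit_exposures(spec,
                                                          signature_matrix)

        base_cnv = cnv_ctdna.call_gains(read_segments(paths.baseline_segments),
                                        gene_intervals,
                                        timepoint=Timepoint.BASELINE)
        res_cnv = cnv_ctdna.call_gains(read_segments(paths.resistance_segments),
                                       gene_intervals,
                                       timepoint=Timepoint.RESISTANCE)
        cnv_compare[pid] = cnv_ctdna.compare_cnv_timepoints(base_cnv, res_cnv)

    gene_results = aggregate_cohort(all_gds, manifest.patients,
                                    min_patients=min_patients,
                                    direction=direction)
    oncoprint = build_oncoprint(all_gds, gene_results, manifest.patients)
    stats = _cohort_statistics(manifest, dynamics, all_gds, gene_results)

    result = PipelineResult(
        manifest=manifest, gene_results=gene_results, oncoprint=oncoprint,
        dynamics=dynamics, gene_dynamics=all_gds, exposures=exposures,
        cnv_compare=cnv_compare, stats=stats, audits=audits,
    )
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def _cohort_statistics(manifest, dynamics, gds, gene_results) -> dict:
    stats: dict[str, object] = {}
    # mutation count (resistance sample, post-filter union side) vs ctDNA fraction
    counts, fracs = [], []
    for p in manifest.patients:
        paths = manifest.pairs[p.patient_id]
        if paths.resistance_tumor_fraction is None:
            continue
        n_res = sum(1 for v in dynamics[p.patient_id] if v.vaf_res > 0)
        counts.append(n_res)
        fracs.append(paths.resistance_tumor_fraction)
    if len(counts) >= 3 and len(set(fracs)) > 1 and len(set(counts)) > 1:
        r, p_val = cohort_stats.pearson(counts, fracs)
        stats["mutations_vs_ctdna_fraction"] = {"r": r, "p": p_val,
                                                "n": len(counts)}
    # survival: most recurrent selected gene, altered vs unaltered
    selected = [g for g in gene_results if g.selected]
    if selected:
        top_gene = selected[0].gene
        try:
            grouping = cohort_stats.survival_by_gene(gds, manifest.patients,
                                                     top_gene)
            stats["survival_top_gene"] = {
                "gene": top_gene,
                "logrank": cohort_stats.logrank(grouping),
            }
        except ValueError:
            pass
    # survival: high vs low ctDNA amount at resistance (median split)
    amounts = []
    for p in manifest.patients:
        paths = manifest.pairs[p.patient_id]
        tf = paths.resistance_tumor_fraction
        cf = paths.resistance_cfdna_amount
        amounts.append(cnv_ctdna.ctdna_amount(tf, cf)
                       if tf is not None and cf is not None else float("nan"))
    try:
        labels = cohort_stats.median_split(amounts)
        grouping = cohort_stats.SurvivalGrouping(
            labels=[l for l in labels if l],
            times=[p.survival_time for p, l in zip(manifest.patients, labels) if l],
            events=[p.event for p, l in zip(manifest.patients, labels) if l],
        )
        stats["survival_ctdna_amount"] = {"logrank": cohort_stats.logrank(grouping)}
    except ValueError:
        pass
    return stats


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort_results(result.gene_results, outdir / "cohort_genes.tsv")
    write_gene_matrix(result.oncoprint, outdir / "oncoprint.tsv")
    rows = []
    for pid in sorted(result.dynamics):
        for v in result.dynamics[pid]:
            rows.append({"patient": pid, "gene": v.gene, "chrom": v.key.chrom,
                         "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
                         "vaf_base": round(v.vaf_base, 6),
                         "vaf_res": round(v.vaf_res, 6),
                         "delta": round(v.delta, 6), "class": v.cls.value})
    pd.DataFrame(rows, columns=["patient", "gene", "chrom", "pos", "ref",
                                "alt", "vaf_base", "vaf_res", "delta",
                                "class"]).to_csv(outdir / "dynamics.tsv",
                                                 sep="\t", index=False)
    if result.exposures:
        write_exposures(result.exposures, outdir / "exposures.tsv")
    hotspots = hotspot_table(result.dynamics)
    hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    cnv_rows = []
    for pid in sorted(result.cnv_compare):
        df = result.cnv_compare[pid]
        for _, row in df.iterrows():
            cnv_rows.append({"patient": pid, "gene": row["gene"],
                             "status": row["status"]})
    pd.DataFrame(cnv_rows, columns=["patient", "gene", "status"]
                 ).to_csv(outdir / "cnv_compare.tsv", sep="\t", index=False)
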