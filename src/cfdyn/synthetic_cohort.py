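"""Seedable generator of paired-cohort inputs for the analysis pipeline.

Emulates the statistical structure of a paired cfDNA exome cohort:
per-sample tumor fractions around 0.15–0.71, per-site depths drawn
negative-binomially around a ~138x sample mean, a 1% VAF detection
floor arising naturally from binomial read sampling, signature-structured
passenger mutations, recurrent planted resistance-emergent driver
variants (shared hotspot protein changes across carriers), germline
polymorphism contamination, synonymous/COSMIC spikes, copy-number
segment tables with planted focal gains, and exponential survival with
a hazard ratio for carriers of planted resistance genes.

The VAF model is copy-neutral heterozygous: expected VAF =
tumor_fraction x CCF / 2.  Observed alt reads are
Binomial(depth, expected VAF + error_rate / 3), so low-tumor-fraction
samples lose low-CCF clones below the detection floor — the mechanism
behind the mutation-count/ctDNA-fraction correlation.

All randomness flows from a single seed through a per-patient generator
hierarchy, so adding patients never perturbs earlier patients' draws and
a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model_io import (
    Annotation, CancerType, CohortManifest, Effect, PatientPaths,
    PatientRecord, Region, Segment, Timepoint, Treatment, Treatment as _T,
    VariantCall, VariantKey, write_annotation_table, write_manifest,
    write_segments, write_vcf_calls,
)
from .signature_refit import (
    BASES, SUBSTITUTIONS, SignatureMatrix, TrinucSpectrum, revcomp,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PlantedGene:
    """A driver variant planted in ``n_carriers`` patients at a shared site.

    ``ccf_base``/``ccf_res`` are the cancer-cell fractions at the two time
    points; the default (0 at baseline, 0.8 at resistance) makes the gene
    resistance-emergent.  All carriers share the same genomic key and
    protein change, emulating a recurrent hotspot.
    """

    gene: str
    protein_change: str
    n_carriers: int
    ccf_res: float = 0.8
    ccf_base: float = 0.0


@dataclass
class PlantedGain:
    """A focal copy-number gain planted in one patient at one time point."""

    patient_index: int
    chrom: str
    start: int          # 0-based half-open
    end: int
    tcn: float = 12.0
    timepoint: Timepoint = Timepoint.RESISTANCE


@dataclass
class SimConfig:
    """Study conditions of the simulated paired cohort.

    Defaults mirror a serial-liquid-biopsy exome study: ~138x mean
    coverage, tumor fractions uniform in [0.15, 0.71], ~50 passenger
    SNVs per sample, a 0.1% sequencing error rate, and exponential
    survival with a threefold hazard for carriers of planted resistance
    genes.
    """

    n_patients: int = 20
    lung_fraction: float = 0.33          # remainder colorectal
    targeted_fraction: float = 0.5       # EGFR-TKI (lung) / cetuximab (CRC)
    depth_mean: float = 138.0
    depth_sample_sd: float = 30.0        # between-sample mean-coverage spread
    depth_dispersion: float = 30.0       # NB size parameter, per site
    tumor_fraction_range: tuple[float, float] = (0.15, 0.71)
    passengers_mean: float = 50.0        # Poisson mean per sample
    passenger_ccf_range: tuple[float, float] = (0.02, 1.0)
    # subclonal-heavy CCF distribution: lo + (hi-lo) * Beta(a, b)
    passenger_ccf_beta: tuple[float, float] = (0.7, 1.5)
    passenger_shared_fraction: float = 0.8   # present at both time points
    planted_resistance: list[PlantedGene] = field(default_factory=list)
    planted_baseline: list[PlantedGene] = field(default_factory=list)
    planted_gains: list[PlantedGain] = field(default_factory=list)
    germline_per_sample: int = 5
    germline_pop_af: float = 0.05
    synonymous_per_sample: int = 3
    synonymous_cosmic_per_sample: int = 1
    error_rate: float = 0.001
    signature_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    n_signatures: int = 5
    gain_tcn: float = 12.0
    baseline_hazard: float = 0.03        # events per month
    hazard_ratio_altered: float = 3.0
    censor_time: float = 60.0            # months
    cfdna_amount_range: tuple[float, float] = (10.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.planted_resistance + self.planted_baseline
        over = [p.gene for p in planted if p.n_carriers > self.n_patients]
        if over:
            raise ValueError(f"more carriers than patients for {over}")


@dataclass
class TruthRecord:
    patient_id: str
    planted: list[dict]          # gene, key, ccf_base, ccf_res
    tumor_fraction_base: float
    tumor_fraction_res: float
    signature_weights: list[float]
    altered: bool                # carries any planted resistance gene


@dataclass
class GroundTruth:
    records: list[TruthRecord]
    signature_matrix: SignatureMatrix

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps({
                    "patient_id": r.patient_id, "planted": r.planted,
                    "tumor_fraction_base": r.tumor_fraction_base,
                    "tumor_fraction_res": r.tumor_fraction_res,
                    "signature_weights": r.signature_weights,
                    "altered": r.altered,
                }, sort_keys=True) + "\n")


def default_planted_genes() -> list[PlantedGene]:
    """Three recurrent resistance-emergent drivers (>= 3 carriers each)
    plus five private decoys, the default end-to-end recovery scenario."""
    planted = [
        PlantedGene("DRVA", "I357S", n_carriers=4),
        PlantedGene("DRVB", "S1597P", n_carriers=3),
        PlantedGene("DRVC", "R7415H", n_carriers=3),
    ]
    planted += [PlantedGene(f"PRIV{i}", f"A{100 + i}V", n_carriers=1)
                for i in range(5)]
    return planted


def synthetic_signature_matrix(n_signatures: int = 5, seed: int = 7,
                               concentration: float = 0.08) -> SignatureMatrix:
    """Random sparse signature profiles (Dirichlet over the 96 contexts).

    A synthetic stand-in for a reference signature catalogue so tests and
    simulations need no external download; low concentration makes the
    profiles well separated.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    names = [f"SYN{i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(names=names, profiles=profiles)


def simulate_spectrum(n_mutations: int, weights, sigs: SignatureMatrix,
                      seed: int | np.random.Generator = 0) -> TrinucSpectrum:
    """Multinomial draw of a 96-context spectrum from a signature mixture."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or abs(w.sum() - 1) > 1e-8:
        raise ValueError("weights must lie on the simplex")
    mixture = sigs.profiles @ w
    counts = rng.multinomial(n_mutations, mixture)
    return TrinucSpectrum(counts=counts)


def _bin_to_variant(bin_idx: int, rng: np.random.Generator,
                    ) -> tuple[str, str, str]:
    """(ref, alt, context) for a 96-bin draw, on a random strand."""
    sub = SUBSTITUTIONS[bin_idx // 16]
    five = BASES[(bin_idx % 16) // 4]
    three = BASES[bin_idx % 4]
    ref, alt = sub[0], sub[2]
    context = five + ref + three
    if rng.random() < 0.5:  # report on the purine strand half the time
        context = revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt, context


def _draw_depth(rng: np.random.Generator, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return max(1, int(rng.negative_binomial(size_param, p)))


def _planted_site(idx: int) -> VariantKey:
    chrom = str((idx % 22) + 1)
    return VariantKey(chrom, 10_000_000 + 1_000 * (idx + 1), "C", "T")


def inject_segments(cfg: SimConfig, patient_index: int,
                    gain_regions: list[PlantedGain]) -> list[Segment]:
    """Whole-genome background at tcn 2 with the planted focal gains cut in.

    Chromosomes are modelled as 100 Mb; each planted region splits its
    background segment into flanking diploid pieces plus the amplified one.
    """
    chrom_len = 100_000_000
    by_chrom: dict[str, list[PlantedGain]] = {}
    for g in gain_regions:
        if g.patient_index == patient_index:
            by_chrom.setdefault(g.chrom, []).append(g)
    segs: list[Segment] = []
    for c in range(1, 23):
        chrom = str(c)
        gains = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        for a, b in zip(gains, gains[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping planted gains on chr{chrom}")
        cursor = 0
        for g in gains:
            if g.start > cursor:
                segs.append(Segment(chrom, cursor, g.start, tcn=2.0, lcn=1.0))
            segs.append(Segment(chrom, g.start, g.end, tcn=g.tcn, lcn=1.0))
            cursor = g.end
        if cursor < chrom_len:
            segs.append(Segment(chrom, cursor, chrom_len, tcn=2.0, lcn=1.0))
    return segs


def _observe(rng: np.random.Generator, tf: float, ccf: float,
             cfg: SimConfig) -> tuple[int, int, float]:
    """(depth, alt_reads, vaf) for one site via binomial read sampling."""
    depth = _draw_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
    p = min(1.0, tf * ccf / 2.0 + cfg.error_rate / 3.0)
    alt = int(rng.binomial(depth, p))
    return depth, alt, alt / depth


def simulate_cohort(cfg: SimConfig, outdir: str | Path,
                    ) -> tuple[CohortManifest, GroundTruth]:
    """Write a full paired cohort (VCFs, annotation tables, trinucleotide
    context tables, segment tables, manifest, ground truth) to ``outdir``.

    Carrier assignment is round-robin over a seeded patient shuffle so
    planted genes overlap in realistic patterns.  Returns the manifest
    and the ground truth (also written as ``truth.jsonl``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sigs = synthetic_signature_matrix(cfg.n_signatures)
    sig_w = np.zeros(cfg.n_signatures)
    w = np.asarray(cfg.signature_weights, dtype=float)
    sig_w[: len(w)] = w / w.sum()

    root = np.random.default_rng([cfg.seed, 0xC0F])
    perm = root.permutation(cfg.n_patients)
    planted_all = list(cfg.planted_resistance) + list(cfg.planted_baseline)
    carriers: dict[int, list[tuple[PlantedGene, VariantKey]]] = {}
    cursor = 0
    for gi, pg in enumerate(planted_all):
        key = _planted_site(gi)
        for _ in range(pg.n_carriers):
            pidx = int(perm[cursor % cfg.n_patients])
            carriers.setdefault(pidx, []).append((pg, key))
            cursor += 1

    res_genes = {p.gene for p in cfg.planted_resistance}
    patients: list[PatientRecord] = []
    pairs: dict[str, PatientPaths] = {}
    truth_records: list[TruthRecord] = []

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, 1, i])
        pid = f"P{i + 1:03d}"
        cancer = (CancerType.LUNG if rng.random() < cfg.lung_fraction
                  else CancerType.COLORECTAL)
        targeted = rng.random() < cfg.targeted_fraction
        treatment = (Treatment.EGFR_TKI if cancer is CancerType.LUNG
                     else Treatment.CETUXIMAB) if targeted else _T.CYTOTOXIC

        tf_lo, tf_hi = cfg.tumor_fraction_range
        tf = {tp: float(rng.uniform(tf_lo, tf_hi))
              for tp in (Timepoint.BASELINE, Timepoint.RESISTANCE)}
        cfdna = {tp: float(rng.uniform(*cfg.cfdna_amount_range))
                 for tp in (Timepoint.BASELINE, Timepoint.RESISTANCE)}

        calls = {Timepoint.BASELINE: [], Timepoint.RESISTANCE: []}
        ann: dict[VariantKey, Annotation] = {}
        contexts: dict[VariantKey, str] = {}
        used_pos: set[tuple[str, int]] = set()

        def new_key(rng: np.random.Generator) -> tuple[VariantKey, str, str]:
            """Random passenger site with a signature-drawn context."""
            bin_idx = int(rng.choice(96, p=sigs.profiles @ sig_w))
            ref, alt, context = _bin_to_variant(bin_idx, rng)
            while True:
                chrom = str(int(rng.integers(1, 23)))
                pos = int(rng.integers(1_000_000, 200_000_000))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            return VariantKey(chrom, pos, ref, alt), context, alt

        def add_call(tp: Timepoint, key: VariantKey, ccf: float,
                     qual: float) -> bool:
            depth, alt, vaf = _observe(rng, tf[tp], ccf, cfg)
            if alt == 0:
                return False
            calls[tp].append(VariantCall(key=key, vaf=vaf, depth=depth,
                                         alt_reads=alt, qual=qual))
            return True

        # planted drivers: shared key + protein change across carriers
        planted_truth = []
        for pg, key in carriers.get(i, []):
            used_pos.add((key.chrom, key.pos))
            contexts[key] = "ACA"
            ann[key] = Annotation(gene=pg.gene, region=Region.EXONIC,
                                  effect=Effect.MISSENSE,
                                  protein_change=pg.protein_change,
                                  pop_af_max=0.0, cosmic_id="")
            if pg.ccf_base > 0:
                add_call(Timepoint.BASELINE, key, pg.ccf_base, qual=60.0)
            if pg.ccf_res > 0:
                add_call(Timepoint.RESISTANCE, key, pg.ccf_res, qual=60.0)
            planted_truth.append({
                "gene": pg.gene, "protein_change": pg.protein_change,
                "chrom": key.chrom, "pos": key.pos,
                "ccf_base": pg.ccf_base, "ccf_res": pg.ccf_res,
            })

        # signature-structured passengers
        n_pass = int(rng.poisson(cfg.passengers_mean))
        for j in range(n_pass):
            key, context, alt = new_key(rng)
            contexts[key] = context
            ann[key] = Annotation(gene=f"PG{rng.integers(0, 5000):04d}",
                                  region=Region.EXONIC, effect=Effect.MISSENSE,
                                  protein_change=f"A{int(rng.integers(10, 999))}V",
                                  pop_af_max=0.0, cosmic_id="")
            lo, hi = cfg.passenger_ccf_range
            ccf = lo + (hi - lo) * float(rng.beta(*cfg.passenger_ccf_beta))
            qual = float(np.clip(rng.normal(60, 15), 0, 99))
            u = rng.random()
            if u < cfg.passenger_shared_fraction:
                add_call(Timepoint.BASELINE, key, ccf, qual)
                add_call(Timepoint.RESISTANCE, key, ccf, qual)
            elif u < cfg.passenger_shared_fraction + 0.1:
                add_call(Timepoint.BASELINE, key, ccf, qual)
            else:
                add_call(Timepoint.RESISTANCE, key, ccf, qual)

        # germline polymorphism contamination (pop AF above the 1% cutoff)
        for j in range(cfg.germline_per_sample):
            key, context, alt = new_key(rng)
            contexts[key] = context
            ann[key] = Annotation(gene=f"GL{j:03d}", region=Region.EXONIC,
                                  effect=Effect.MISSENSE, protein_change="",
                                  pop_af_max=cfg.germline_pop_af, cosmic_id="")
            for tp in (Timepoint.BASELINE, Timepoint.RESISTANCE):
                depth = _draw_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
                alt_n = int(rng.binomial(depth, 0.5))
                if alt_n:
                    calls[tp].append(VariantCall(
                        key=key, vaf=alt_n / depth, depth=depth,
                        alt_reads=alt_n, qual=60.0))

        # synonymous spikes, a subset carrying a COSMIC id
        for j in range(cfg.synonymous_per_sample):
            key, context, alt = new_key(rng)
            contexts[key] = context
            cosmic = (f"COSM{1000 + i * 10 + j}"
                      if j < cfg.synonymous_cosmic_per_sample else "")
            ann[key] = Annotation(gene=f"SYNG{i:03d}_{j}", region=Region.EXONIC,
                                  effect=Effect.SYNONYMOUS, protein_change="",
                                  pop_af_max=0.0, cosmic_id=cosmic)
            ccf = float(rng.uniform(0.3, 1.0))
            add_call(Timepoint.BASELINE, key, ccf, qual=60.0)
            add_call(Timepoint.RESISTANCE, key, ccf, qual=60.0)

        # files
        paths = PatientPaths(
            baseline_vcf=str(outdir / f"{pid}_base.vcf"),
            resistance_vcf=str(outdir / f"{pid}_res.vcf"),
            baseline_annotation=str(outdir / f"{pid}_base.ann.tsv"),
            resistance_annotation=str(outdir / f"{pid}_res.ann.tsv"),
            baseline_segments=str(outdir / f"{pid}_base.seg.tsv"),
            resistance_segments=str(outdir / f"{pid}_res.seg.tsv"),
            contexts=str(outdir / f"{pid}.contexts.tsv"),
            baseline_tumor_fraction=round(tf[Timepoint.BASELINE], 4),
            resistance_tumor_fraction=round(tf[Timepoint.RESISTANCE], 4),
            baseline_cfdna_amount=round(cfdna[Timepoint.BASELINE], 2),
            resistance_cfdna_amount=round(cfdna[Timepoint.RESISTANCE], 2),
        )
        write_vcf_calls(calls[Timepoint.BASELINE], paths.baseline_vcf,
                        f"{pid}_base")
        write_vcf_calls(calls[Timepoint.RESISTANCE], paths.resistance_vcf,
                        f"{pid}_res")
        for tp, ann_path in ((Timepoint.BASELINE, paths.baseline_annotation),
                             (Timepoint.RESISTANCE, paths.resistance_annotation)):
            keys = {c.key for c in calls[tp]}
            write_annotation_table({k: ann[k] for k in keys}, ann_path)
        for tp, seg_path in ((Timepoint.BASELINE, paths.baseline_segments),
                             (Timepoint.RESISTANCE, paths.resistance_segments)):
            gains = [g for g in cfg.planted_gains if g.timepoint is tp]
            write_segments(inject_segments(cfg, i, gains), seg_path)
        _write_contexts(contexts, outdir / f"{pid}.contexts.tsv")

        # survival: exponential, hazard scaled up for resistance-gene carriers
        altered = any(pg.gene in res_genes for pg, _ in carriers.get(i, []))
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio_altered if altered
                                        else 1.0)
        t_event = float(rng.exponential(1.0 / hazard))
        survival_time = min(t_event, cfg.censor_time)
        event = int(t_event <= cfg.censor_time)

        patients.append(PatientRecord(
            patient_id=pid, cancer_type=cancer, treatment=treatment,
            survival_time=round(survival_time, 3), event=event,
            residual_tumor_size=(None if rng.random() < 0.2
                                 else round(float(rng.uniform(5, 80)), 1)),
        ))
        pairs[pid] = paths
        truth_records.append(TruthRecord(
            patient_id=pid, planted=planted_truth,
            tumor_fraction_base=tf[Timepoint.BASELINE],
            tumor_fraction_res=tf[Timepoint.RESISTANCE],
            signature_weights=[float(x) for x in sig_w],
            altered=altered,
        ))

    manifest = CohortManifest(patients=patients, pairs=pairs)
    write_manifest(manifest, outdir / "manifest.yaml")
    truth = GroundTruth(records=truth_records, signature_matrix=sigs)
    truth.write(outdir / "truth.jsonl")
    return manifest, truth


def _write_contexts(contexts: dict[VariantKey, str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcontext\n")
        for key in sorted(contexts):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{contexts[key]}\n")


def read_contexts(path: str | Path) -> dict[VariantKey, str]:
    out: dict[VariantKey, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, pos, ref, alt, context = line.rstrip("\n").split("\t")
            out[VariantKey(chrom, int(pos), ref, alt)] = context
    return out
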