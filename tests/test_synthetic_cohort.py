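"""Simulator contracts: determinism, planted-truth fidelity, and the
statistical structure the downstream analysis assumes."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from cfdyn import (
    PlantedGain, PlantedGene, SimConfig, Timepoint, call_gains,
    compare_cnv_timepoints, default_planted_genes, inject_segments,
    pair_variants, read_manifest, read_segments, simulate_cohort,
    simulate_spectrum, synthetic_signature_matrix,
)
from cfdyn.data_model_io import load_sample
from cfdyn.cnv_ctdna import GeneInterval
from cfdyn.variant_filter import FilterConfig, filter_sample


def _load_pair(manifest, pid):
    paths = manifest.pairs[pid]
    base = load_sample(paths.baseline_vcf, paths.baseline_annotation,
                       f"{pid}_base", pid, Timepoint.BASELINE)
    res = load_sample(paths.resistance_vcf, paths.resistance_annotation,
                      f"{pid}_res", pid, Timepoint.RESISTANCE)
    return base, res


def test_zero_patients_empty_manifest(tmp_path):
    manifest, truth = simulate_cohort(SimConfig(n_patients=0, seed=1), tmp_path)
    assert manifest.patients == [] and truth.records == []


def test_more_carriers_than_patients_rejected():
    with pytest.raises(ValueError, match="carriers"):
        SimConfig(n_patients=2,
                  planted_resistance=[PlantedGene("G", "A1V", n_carriers=3)])


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(n_patients=4, seed=42,
                    planted_resistance=[PlantedGene("D", "A1V", 2)])
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_cohort(cfg, d1)
    simulate_cohort(cfg, d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    for name in files1:
        if name == "manifest.yaml":
            # paths embed the directory; compare everything else verbatim
            continue
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_adding_patients_preserves_earlier_draws(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_cohort(SimConfig(n_patients=3, seed=9), d1)
    simulate_cohort(SimConfig(n_patients=5, seed=9), d2)
    for name in ("P001_base.vcf", "P003_res.vcf", "P002.contexts.tsv"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_planted_vaf_matches_binomial_expectation(tmp_path):
    """Gene planted at CCF 0.8 with tumor fraction 0.3: expected VAF 0.12;
    observed carrier mean within +-0.03 over 20 seeds."""
    vafs = []
    for seed in range(20):
        cfg = SimConfig(n_patients=3, seed=seed, depth_mean=150.0,
                        tumor_fraction_range=(0.3, 0.3), passengers_mean=2.0,
                        germline_per_sample=0, synonymous_per_sample=0,
                        planted_resistance=[PlantedGene("G", "A1V", 3,
                                                        ccf_res=0.8)])
        manifest, truth = simulate_cohort(cfg, tmp_path / f"s{seed}")
        for pid in manifest.pairs:
            _, res = _load_pair(manifest, pid)
            vafs.extend(c.vaf for c in res.calls if c.gene == "G")
    assert len(vafs) == 60
    assert abs(np.mean(vafs) - 0.12) <= 0.03


def test_germline_spikes_removed_at_population_stage(default_cohort):
    d, cfg, manifest, _ = default_cohort
    for pid in list(manifest.pairs)[:5]:
        base, res = _load_pair(manifest, pid)
        for sample in (base, res):
            n_germline = sum(1 for c in sample.calls if c.pop_af_max > 0.01)
            _, audit = filter_sample(sample, FilterConfig())
            assert audit.counts["population_af"] == n_germline
            assert n_germline == cfg.germline_per_sample


def test_mutation_count_tracks_tumor_fraction(default_cohort):
    """Post-filter mutation counts correlate positively with the configured
    tumor fraction across the 40 samples (fraction-dependent detection)."""
    from cfdyn import pearson
    d, cfg, manifest, truth = default_cohort
    tf_by = {r.patient_id: r for r in truth.records}
    counts, fracs = [], []
    for pid in manifest.pairs:
        base, res = _load_pair(manifest, pid)
        for sample, tf in ((base, tf_by[pid].tumor_fraction_base),
                           (res, tf_by[pid].tumor_fraction_res)):
            filtered, _ = filter_sample(sample, FilterConfig())
            counts.append(len(filtered.calls))
            fracs.append(tf)
    r, _ = pearson(counts, fracs)
    assert r > 0.3


def test_planted_genes_resistance_emergent(default_cohort):
    d, cfg, manifest, truth = default_cohort
    planted_carriers = {(r.patient_id, p["gene"])
                        for r in truth.records for p in r.planted
                        if p["ccf_res"] > 0 and p["ccf_base"] == 0}
    found = set()
    for pid in manifest.pairs:
        base, res = _load_pair(manifest, pid)
        base_f, _ = filter_sample(base)
        res_f, _ = filter_sample(res)
        for v in pair_variants(base_f, res_f):
            if (pid, v.gene) in planted_carriers:
                assert v.cls.resistance_direction
                found.add((pid, v.gene))
    assert found == planted_carriers


class TestSimulateSpectrum:
    def test_single_signature_support(self, sigs5):
        w = np.array([1.0, 0, 0, 0, 0])
        spec = simulate_spectrum(500, w, sigs5, seed=3)
        support = sigs5.profiles[:, 0] > 0
        assert spec.counts[~support].sum() == 0

    def test_zero_mutations(self, sigs5):
        spec = simulate_spectrum(0, np.array([1.0, 0, 0, 0, 0]), sigs5, seed=3)
        assert spec.total == 0

    def test_large_sample_converges_to_mixture(self, sigs5):
        w = np.array([0.5, 0.5, 0, 0, 0])
        spec = simulate_spectrum(100_000, w, sigs5, seed=3)
        empirical = spec.counts / spec.total
        assert np.abs(empirical - sigs5.profiles @ w).max() < 0.01

    def test_off_simplex_rejected(self, sigs5):
        with pytest.raises(ValueError):
            simulate_spectrum(10, np.array([0.5, 0.2, 0, 0, 0]), sigs5)


class TestInjectSegments:
    GENE = [GeneInterval("MYC", "8", 127_000_000, 127_100_000)]

    def test_background_diploid_no_gains(self):
        segs = inject_segments(SimConfig(seed=0), 0, [])
        assert all(s.tcn == 2.0 for s in segs)
        assert not any(c.gain for c in call_gains(segs, self.GENE))

    def test_planted_region_yields_one_gain(self):
        gains = [PlantedGain(0, "8", 126_000_000, 128_000_000, tcn=12.0)]
        segs = inject_segments(SimConfig(seed=0), 0, gains)
        calls = call_gains(segs, self.GENE)
        assert sum(c.gain for c in calls) == 1
        assert {g for c in calls if c.gain for g in c.genes} == {"MYC"}

    def test_boundary_tcn_8_not_gained(self):
        gains = [PlantedGain(0, "8", 126_000_000, 128_000_000, tcn=8.0)]
        segs = inject_segments(SimConfig(seed=0), 0, gains)
        assert not any(c.gain for c in call_gains(segs, self.GENE))

    def test_written_tables_roundtrip_to_res_only_gain(self, tmp_path):
        cfg = SimConfig(n_patients=1, seed=5, passengers_mean=3.0,
                        planted_gains=[PlantedGain(0, "8", 126_000_000,
                                                   128_000_000)])
        manifest, _ = simulate_cohort(cfg, tmp_path)
        paths = manifest.pairs["P001"]
        base = call_gains(read_segments(paths.baseline_segments), self.GENE)
        res = call_gains(read_segments(paths.resistance_segments), self.GENE)
        df = compare_cnv_timepoints(base, res)
        assert df.to_dict("records") == [{"gene": "MYC", "status": "res_only"}]
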