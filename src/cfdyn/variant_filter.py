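"""Somatic-variant filter cascade with a per-stage audit trail.

The cascade applies, in a fixed order, the hard filters used for
cfDNA exome call sets: call quality, total depth, alt-supporting reads,
the 1% VAF detection floor, restriction to exonic/splicing regions,
the 1% population-frequency polymorphism cutoff, and removal of
synonymous variants unless they carry a COSMIC id.  The surviving set
is the conjunction of all predicates, so it does not depend on stage
order; only the audit's attribution of removals does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .data_model_io import Effect, Region, SampleCallset, VariantCall, VariantKey

STAGE_NAMES = (
    "quality", "depth", "alt_reads", "vaf_floor",
    "region", "population_af", "synonymous",
)


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    Defaults follow the cfDNA exome convention: QUAL >= 30, depth >= 20,
    >= 3 supporting reads, 1% VAF detection floor, exonic/splicing only,
    <= 1% population frequency, and synonymous variants dropped unless
    they have a COSMIC id.  ``min_vaf=0`` disables the detection floor.
    """

    min_qual: float = 30.0
    min_depth: int = 20
    min_alt_reads: int = 3
    min_vaf: float = 0.01
    keep_regions: frozenset[Region] = frozenset({Region.EXONIC, Region.SPLICING})
    max_pop_af: float = 0.01
    synonymous_cosmic_exception: bool = True
    blacklist: frozenset[VariantKey] = frozenset()

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_depth, self.min_alt_reads,
               self.max_pop_af) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")


@dataclass
class FilterAudit:
    """Per-stage removal counts; a call removed at stage k is not counted later."""

    counts: dict[str, int]
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != sum(self.counts.values()):
            raise ValueError("audit counts inconsistent with n_in/n_out")


def _failing_stage(c: VariantCall, cfg: FilterConfig) -> str | None:
    """Name of the first cascade stage the call fails, or None if it passes."""
    if c.qual < cfg.min_qual:
        return "quality"
    if c.depth < cfg.min_depth:
        return "depth"
    if c.alt_reads < cfg.min_alt_reads:
        return "alt_reads"
    if c.vaf < cfg.min_vaf:
        return "vaf_floor"
    if c.region not in cfg.keep_regions:
        return "region"
    if c.pop_af_max > cfg.max_pop_af:
        return "population_af"
    if (c.effect is Effect.SYNONYMOUS
            and not (cfg.synonymous_cosmic_exception and c.cosmic_id)):
        return "synonymous"
    if c.key in cfg.blacklist:
        return "blacklist"
    return None


def apply_filter_cascade(calls: list[VariantCall],
                         cfg: FilterConfig | None = None,
                         ) -> tuple[list[VariantCall], FilterAudit]:
    """Apply the cascade; return surviving calls and the per-stage audit.

    Unannotated calls fail the region stage (region defaults to OTHER).
    An optional blacklist stage (site list standing in for manual BAM
    review) runs last and is only reported when it removes anything.
    """
    cfg = cfg or FilterConfig()
    counts = {name: 0 for name in STAGE_NAMES}
    if cfg.blacklist:
        counts["blacklist"] = 0
    passing: list[VariantCall] = []
    for c in calls:
        stage = _failing_stage(c, cfg)
        if stage is None:
            passing.append(c)
        else:
            counts[stage] += 1
    audit = FilterAudit(counts=counts, n_in=len(calls), n_out=len(passing))
    return passing, audit


def filter_sample(s: SampleCallset, cfg: FilterConfig | None = None,
                  ) -> tuple[SampleCallset, FilterAudit]:
    """Filter one sample's calls; sample metadata is unchanged."""
    passing, audit = apply_filter_cascade(s.calls, cfg)
    return replace(s, calls=passing), audit


def write_audit(audit: FilterAudit, path) -> None:
    """Write the audit as a two-column TSV (stage, removed)."""
    with open(path, "w") as fh:
        fh.write("stage\tremoved\n")
        for stage, n in audit.counts.items():
            fh.write(f"{stage}\t{n}\n")
        fh.write(f"total_in\t{audit.n_in}\ntotal_out\t{audit.n_out}\n")
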