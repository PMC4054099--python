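"""The driver-prioritization cascade.

Sample level: tumours carrying a mutated and expressed known cancer gene
already have a plausible driver and are discarded, as are tumours with
no expression data for any mutated gene. Gene level, for each retained
tumour, a mutated gene is a putative driver iff it is

1. expressed in that tumour,
2. damagingly mutated (truncating class, or 2-of-3 missense consensus),
3. short (coding length < 4,450 bp, the top-5% cut of human coding
   lengths) — longer genes survive only if mutated in few cancer types,
   which separates genuinely recurrent drivers from genes that collect
   passengers because of their size,
4. cancer-gene-like in at least ``min_systems_true`` of the four
   systems properties (central hub, cancer interactor, cancer-like
   origin, singleton).

Every gene receives an auditable trace recording its first failure
stage; the report is deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .errors import ValidationError
from .mutation_effects import DamagingCall, damaging_call
from .records import CohortBundle, EXPRESSED, NO_DATA, report_to_json
from .systems import (
    DEFAULT_CANCER_LIKE_EPOCHS,
    SystemsProfile,
    compute_centralities,
    hub_thresholds,
    passes_systems_filter,
    systems_profile,
)

logger = logging.getLogger("driverlens")

STAGES = ("unannotated", "expression", "damaging", "length", "systems")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the cascade.

    Defaults reproduce the published operating point: detection alpha
    0.05, SIFT > 0.95 / PolyPhen > 0.9, length cut 4,450 bp with long
    genes retained iff mutated in fewer than five cancer types, hub cut
    at the 75th percentile, and a 2-of-4 systems rule. ``long_gene_rule``
    selects between the two printed readings of the recurrence cutoff
    ("methods": retain iff < 5 types; "results": retain iff <= 5).
    ``exempt_known`` re-admits samples mutated in the listed known genes
    so the cascade can call them (the tumour-suppressor recovery
    experiment).
    """

    alpha_detection: float = 0.05
    sift_thr: float = 0.95
    polyphen_thr: float = 0.9
    length_thr_bp: int = 4450
    max_cancer_types_for_long: int = 4
    long_gene_rule: str = "methods"
    hub_quantile: float = 0.75
    min_systems_true: int = 2
    require_known_expressed: bool = True
    exempt_known: frozenset = frozenset()
    cancer_like_epochs: frozenset = DEFAULT_CANCER_LIKE_EPOCHS
    yates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.long_gene_rule not in ("methods", "results"):
            raise ValidationError(f"unknown long_gene_rule {self.long_gene_rule!r}")
        if not (0 <= self.min_systems_true <= 4):
            raise ValidationError("min_systems_true must be in [0, 4]")
        if self.length_thr_bp < 1:
            raise ValidationError("length_thr_bp must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)!r}")
        kwargs = dict(mapping)
        for key in ("exempt_known", "cancer_like_epochs"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)


@dataclass
class GeneFilterTrace:
    sample_id: str
    gene_id: str
    expressed: str  # expressed | not_expressed | no_data
    damaging: Optional[DamagingCall]
    length_ok: Optional[bool]
    systems: Optional[SystemsProfile]
    final_driver: bool
    failure_stage: Optional[str]


@dataclass
class DriverCallReport:
    retained_samples: List[str]
    discarded_samples: Dict[str, str]  # sample -> reason
    drivers_by_sample: Dict[str, List[str]]
    traces: List[GeneFilterTrace]
    config: PipelineConfig
    summary: Dict = field(default_factory=dict)

    def all_driver_genes(self) -> List[str]:
        return sorted({g for genes in self.drivers_by_sample.values() for g in genes})

    def driver_pairs(self) -> Set[Tuple[str, str]]:
        return {
            (s, g) for s, genes in self.drivers_by_sample.items() for g in genes
        }

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.traces:
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "gene_id": t.gene_id,
                    "expressed": t.expressed,
                    "damaging": t.damaging.is_damaging if t.damaging else None,
                    "damaging_basis": t.damaging.basis if t.damaging else None,
                    "length_ok": t.length_ok,
                    "systems_n_true": t.systems.n_true if t.systems else None,
                    "final_driver": t.final_driver,
                    "failure_stage": t.failure_stage or "",
                }
            )
        return pd.DataFrame(rows).sort_values(["sample_id", "gene_id"]).reset_index(drop=True)

    def to_json(self) -> str:
        payload = {
            "retained_samples": sorted(self.retained_samples),
            "discarded_samples": dict(sorted(self.discarded_samples.items())),
            "drivers_by_sample": {
                s: sorted(g) for s, g in sorted(self.drivers_by_sample.items())
            },
            "summary": self.summary,
        }
        return report_to_json(payload)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        drivers = [
            {"sample_id": s, "gene_id": g}
            for s in sorted(self.drivers_by_sample)
            for g in self.drivers_by_sample[s]
        ]
        pd.DataFrame(drivers, columns=["sample_id", "gene_id"]).to_csv(
            outdir / "drivers.tsv", sep="\t", index=False
        )
        self.traces_frame().to_csv(outdir / "traces.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.discarded_samples.items()), columns=["sample_id", "reason"]
        ).to_csv(outdir / "discarded_samples.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(self.to_json() + "\n")


def filter_samples(
    cohort: CohortBundle, config: PipelineConfig
) -> Tuple[List[str], Dict[str, str]]:
    """Sample-level triage.

    Discards a sample when (a) a known cancer gene outside
    ``exempt_known`` is mutated in it and — if ``require_known_expressed``
    — called expressed in it, or (b) every mutated gene has a no_data
    call. Samples without mutations are discarded with reason
    "no_mutations".
    """
    by_sample = cohort.mutations_by_sample()
    blocking_known = cohort.known_cancer_set - config.exempt_known
    retained, discarded = [], {}
    for sample in sorted(set(by_sample) | set(cohort.sample_to_cancer_type)):
        muts = by_sample.get(sample, [])
        if not muts:
            discarded[sample] = "no_mutations"
            continue
        genes = sorted({m.gene_id for m in muts})
        known_hit = False
        for gene in genes:
            if gene not in blocking_known:
                continue
            if not config.require_known_expressed:
                known_hit = True
                break
            if cohort.expression.call(sample, gene) == EXPRESSED:
                known_hit = True
                break
        if known_hit:
            discarded[sample] = "known_gene"
            continue
        calls = [cohort.expression.call(sample, g) for g in genes]
        if all(c == NO_DATA for c in calls):
            discarded[sample] = "no_expression_data"
            continue
        retained.append(sample)
    logger.info("retained %d samples, discarded %d", len(retained), len(discarded))
    return retained, discarded


def _length_stage_ok(gene, config: PipelineConfig) -> bool:
    if gene.coding_length_bp < config.length_thr_bp:
        return True
    if config.long_gene_rule == "methods":
        return gene.n_cancer_types_mutated <= config.max_cancer_types_for_long
    return gene.n_cancer_types_mutated <= config.max_cancer_types_for_long + 1


def run_pipeline(cohort: CohortBundle, config: Optional[PipelineConfig] = None) -> DriverCallReport:
    """Run the full cascade and return an auditable report.

    Hub thresholds are computed once on the full network before any
    per-gene decision. Within a retained sample each mutated gene is
    traced through the stages in order; its trace records the first
    failure. A gene mutated several times in a sample is damaging if
    any of its events is.
    """
    config = config or PipelineConfig()
    centralities = compute_centralities(cohort.network)
    thresholds = hub_thresholds(centralities, quantile=config.hub_quantile)
    retained, discarded = filter_samples(cohort, config)

    by_sample = cohort.mutations_by_sample()
    traces: List[GeneFilterTrace] = []
    drivers_by_sample: Dict[str, List[str]] = {}
    profile_cache: Dict[str, SystemsProfile] = {}

    for sample in retained:
        sample_drivers = []
        muts_by_gene: Dict[str, list] = {}
        for m in by_sample[sample]:
            muts_by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id in sorted(muts_by_gene):
            record = cohort.genes.get(gene_id)
            call = cohort.expression.call(sample, gene_id)
            if record is None:
                traces.append(
                    GeneFilterTrace(sample, gene_id, call, None, None, None, False, "unannotated")
                )
                continue
            if call != EXPRESSED:
                traces.append(
                    GeneFilterTrace(sample, gene_id, call, None, None, None, False, "expression")
                )
                continue
            calls = [
                damaging_call(m, sift_thr=config.sift_thr, polyphen_thr=config.polyphen_thr)
                for m in muts_by_gene[gene_id]
            ]
            best = max(calls, key=lambda c: (c.is_damaging, c.votes))
            if not best.is_damaging:
                traces.append(
                    GeneFilterTrace(sample, gene_id, call, best, None, None, False, "damaging")
                )
                continue
            length_ok = _length_stage_ok(record, config)
            if not length_ok:
                traces.append(
                    GeneFilterTrace(sample, gene_id, call, best, False, None, False, "length")
                )
                continue
            if gene_id not in profile_cache:
                profile_cache[gene_id] = systems_profile(
                    record,
                    cohort.network,
                    thresholds,
                    cohort.known_cancer_set,
                    centralities,
                    config.cancer_like_epochs,
                )
            profile = profile_cache[gene_id]
            if not passes_systems_filter(profile, config.min_systems_true):
                traces.append(
                    GeneFilterTrace(sample, gene_id, call, best, True, profile, False, "systems")
                )
                continue
            traces.append(
                GeneFilterTrace(sample, gene_id, call, best, True, profile, True, None)
            )
            sample_drivers.append(gene_id)
        drivers_by_sample[sample] = sorted(sample_drivers)

    report = DriverCallReport(
        retained_samples=sorted(retained),
        discarded_samples=discarded,
        drivers_by_sample=drivers_by_sample,
        traces=traces,
        config=config,
    )
    n_with_driver = sum(1 for g in drivers_by_sample.values() if g)
    report.summary = {
        "n_samples": len(retained) + len(discarded),
        "n_retained": len(retained),
        "n_discarded": len(discarded),
        "discard_reasons": {
            reason: sum(1 for r in discarded.values() if r == reason)
            for reason in sorted(set(discarded.values()))
        },
        "n_samples_with_driver": n_with_driver,
        "n_driver_genes_unique": len(report.all_driver_genes()),
        "n_driver_calls": sum(len(g) for g in drivers_by_sample.values()),
        "hub_degree_thr": thresholds.degree_thr,
        "hub_betweenness_thr": thresholds.betweenness_thr,
    }
    return report


def evaluate_recovery(
    report: DriverCallReport, truth: Mapping[str, Set[str]]
) -> Tuple[Dict[str, bool], float]:
    """Per-sample planted-driver recovery and overall sensitivity.

    A sample is a hit iff at least one of its planted drivers appears in
    its reported list; samples discarded at triage are misses.
    """
    if not truth:
        raise ValidationError("empty truth map")
    hits = {}
    for sample, planted in truth.items():
        reported = set(report.drivers_by_sample.get(sample, []))
        hits[sample] = bool(reported & set(planted))
    sensitivity = sum(hits.values()) / len(hits)
    return hits, sensitivity
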