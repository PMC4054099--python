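"""Seeded generator of complete synthetic tumour cohorts with ground truth.

The generator emulates the statistical structure the driver cascade
assumes, so the whole analysis can be exercised without any external
download:

* coding lengths are log-normal, with the documented 4,450 bp cut
  falling near the top 5% of the distribution;
* passenger mutations strike each gene with probability proportional to
  its coding length, which reproduces the length-recurrence bias;
* expression is probe-based: expressed gene/sample pairs draw detection
  p-values from Uniform(0, alpha), silent pairs from Uniform(alpha, 1),
  so the at-least-half-of-probes rule recovers the planted state;
* the interaction network grows by preferential attachment
  (heavy-tailed degrees, as in the curated interactome);
* a configured fraction of samples carries a mutated-and-expressed
  known cancer gene (exercising the sample triage); the remaining
  "clean" samples receive planted drivers constructed to pass every
  stage: expressed in their sample, frameshift-mutated (or 2-of-3
  damaging missense in ``driver_mutation_class="missense"`` mode),
  shorter than the length cut, of metazoan origin and single-copy
  (hence at least 2 of 4 systems properties);
* the shRNA screen draws positive abundances with planted suppressors
  shifted upward in the cell-line replicates relative to the DNA pool.

Known genes never receive passenger mutations, so the sample triage
discards exactly the constructed fraction of known-driver samples.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io as dio
from .errors import ValidationError
from .expression import call_expression
from .records import (
    CohortBundle,
    EXPRESSED,
    ExpressionCallMatrix,
    GeneRecord,
    MutationRecord,
    NO_DATA,
    NOT_EXPRESSED,
    ORIGIN_EPOCHS,
)
from .shrna import ShrnaScreen


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are the cohort conditions used throughout.

    100 samples of one cancer type over 2,000 genes, ~2% known cancer
    genes, 90% of samples carrying a known mutated-and-expressed driver,
    two planted drivers per clean sample, and a passenger rate giving a
    realistic few dozen coding mutations per exome.
    """

    n_samples: int = 100
    n_genes: int = 2000
    n_tissues: int = 109
    probes_per_gene: Tuple[int, int] = (1, 5)
    fraction_known: float = 0.02
    fraction_no_expression_data: float = 0.15
    n_planted_drivers_per_clean_sample: int = 2
    fraction_samples_with_known_driver: float = 0.9
    fraction_clean_with_driver: float = 1.0
    passenger_rate_per_bp: float = 1.8e-5
    passenger_damaging_fraction: float = 0.3
    length_log_mean: float = math.log(1300.0)
    length_log_sd: float = 0.75
    driver_max_length_bp: int = 4450
    driver_mutation_class: str = "frameshift"
    network_attachment: int = 2
    network_fraction: float = 0.7
    n_cell_lines: int = 5
    replicates_per_line: int = 2
    pool_replicates: int = 2
    screen_probes_per_gene: int = 5
    screen_noise_sd: float = 0.3
    suppressor_effect: float = 1.0
    n_suppressors: int = 50
    expression_breadth_range: Tuple[float, float] = (0.1, 0.9)
    alpha_detection: float = 0.05
    cancer_type: str = "ovarian"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_tissues) < 1:
            raise ValidationError("counts must be >= 1")
        for name in (
            "fraction_known",
            "fraction_no_expression_data",
            "fraction_samples_with_known_driver",
            "fraction_clean_with_driver",
            "passenger_damaging_fraction",
            "network_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValidationError("probes_per_gene must be a (low, high) range with low >= 1")
        if self.driver_mutation_class not in ("frameshift", "missense"):
            raise ValidationError("driver_mutation_class must be frameshift or missense")
        if self.passenger_rate_per_bp < 0:
            raise ValidationError("passenger_rate_per_bp must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: drivers per clean sample, screen suppressors."""

    drivers: Dict[str, FrozenSet[str]]
    suppressors: FrozenSet[str]


def generate_network(n_nodes: int, attachment: int, seed: int) -> nx.Graph:
    """Connected preferential-attachment graph with integer nodes 0..n-1."""
    if attachment < 1 or n_nodes < attachment + 1:
        raise ValidationError("need n_nodes >= attachment + 1 and attachment >= 1")
    return nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)


def _benign_missense(rng) -> dict:
    return {
        "sift_damage_score": float(rng.uniform(0.0, 0.9)),
        "polyphen_score": float(rng.uniform(0.0, 0.85)),
        "mutation_taster_call": "polymorphism",
    }


def _damaging_missense(rng) -> dict:
    return {
        "sift_damage_score": float(rng.uniform(0.96, 1.0)),
        "polyphen_score": float(rng.uniform(0.91, 1.0)),
        "mutation_taster_call": "disease_causing",
    }


def generate(config: SyntheticConfig) -> Tuple[CohortBundle, GroundTruth]:
    """Build a full cohort bundle plus its ground truth. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    lengths = np.clip(
        np.rint(rng.lognormal(config.length_log_mean, config.length_log_sd, config.n_genes)),
        150,
        None,
    ).astype(int)

    n_known = max(1, round(config.fraction_known * config.n_genes))
    known = set(rng.choice(genes, size=n_known, replace=False))
    non_known = np.array([g for g in genes if g not in known])

    n_nodata = round(config.fraction_no_expression_data * config.n_genes)
    if n_nodata > len(non_known):
        raise ValidationError("fraction_no_expression_data leaves no measurable genes")
    nodata = set(rng.choice(non_known, size=n_nodata, replace=False))
    has_data = np.array([g not in nodata for g in genes])
    length_of = dict(zip(genes, lengths))

    pool = np.array(
        [g for g in non_known if g not in nodata and length_of[g] < config.driver_max_length_bp]
    )
    if config.n_planted_drivers_per_clean_sample > len(pool):
        raise ValidationError("more planted drivers per sample than eligible genes")

    # --- sample roles -----------------------------------------------------
    n_known_samples = round(config.fraction_samples_with_known_driver * config.n_samples)
    order = rng.permutation(config.n_samples)
    known_samples = sorted(samples[i] for i in order[:n_known_samples])
    clean_samples = sorted(samples[i] for i in order[n_known_samples:])
    n_driver_samples = round(config.fraction_clean_with_driver * len(clean_samples))
    driver_samples = sorted(
        rng.choice(np.array(clean_samples), size=n_driver_samples, replace=False)
    ) if clean_samples else []

    # --- planted events ---------------------------------------------------
    known_arr = np.array(sorted(known))
    known_events = {s: str(rng.choice(known_arr)) for s in known_samples}
    planted: Dict[str, FrozenSet[str]] = {
        s: frozenset(
            str(g)
            for g in rng.choice(pool, config.n_planted_drivers_per_clean_sample, replace=False)
        )
        for s in driver_samples
    }
    anchor_pool = np.array([g for g in non_known if g not in nodata])
    anchors = {
        s: str(rng.choice(anchor_pool))
        for s in clean_samples
        if s not in planted
    }

    # --- expression state -------------------------------------------------
    lo, hi = config.expression_breadth_range
    p_expr = rng.uniform(lo, hi, config.n_genes)
    state = rng.random((config.n_samples, config.n_genes)) < p_expr
    state[:, ~has_data] = False
    col = {g: j for j, g in enumerate(genes)}
    row = {s: i for i, s in enumerate(samples)}
    for s, g in known_events.items():
        state[row[s], col[g]] = True
    for s, gs in planted.items():
        for g in gs:
            state[row[s], col[g]] = True

    # --- mutations --------------------------------------------------------
    mutations = []
    for s in known_samples:
        mutations.append(MutationRecord(s, known_events[s], "frameshift"))
    for s in sorted(planted):
        for g in sorted(planted[s]):
            if config.driver_mutation_class == "frameshift":
                mutations.append(MutationRecord(s, g, "frameshift"))
            else:
                mutations.append(MutationRecord(s, g, "missense", **_damaging_missense(rng)))
    for s, g in sorted(anchors.items()):
        mutations.append(MutationRecord(s, g, "synonymous"))

    p_mut = np.clip(config.passenger_rate_per_bp * lengths, 0.0, 1.0)
    p_mut[[col[g] for g in known]] = 0.0
    hit = rng.random((config.n_samples, config.n_genes)) < p_mut
    taken = {(s, g) for s, g in known_events.items()}
    taken |= {(s, g) for s, gs in planted.items() for g in gs}
    taken |= set(anchors.items())
    for i, j in np.argwhere(hit):
        s, g = samples[i], str(genes[j])
        if (s, g) in taken:
            continue
        if rng.random() < config.passenger_damaging_fraction:
            if rng.random() < 0.5:
                cls = str(rng.choice(["frameshift", "nonsense", "splice_site"]))
                mutations.append(MutationRecord(s, g, cls))
            else:
                mutations.append(MutationRecord(s, g, "missense", **_damaging_missense(rng)))
        else:
            u = rng.random()
            if u < 0.3:
                mutations.append(MutationRecord(s, g, "synonymous"))
            elif u < 0.4:
                mutations.append(MutationRecord(s, g, "other"))
            else:
                mutations.append(MutationRecord(s, g, "missense", **_benign_missense(rng)))

    # --- probe detection table and levels ---------------------------------
    plo, phi = config.probes_per_gene
    data_idx = np.flatnonzero(has_data)
    n_probes = rng.integers(plo, phi + 1, size=len(data_idx))
    probe_gene_idx = np.repeat(data_idx, n_probes)
    probe_ids = np.concatenate(
        [
            [f"{genes[j]}_p{k}" for k in range(n_probes[t])]
            for t, j in enumerate(data_idx)
        ]
    )
    n_probe = len(probe_ids)
    u = rng.random((n_probe, config.n_samples))
    probe_state = state[:, probe_gene_idx].T  # n_probe x n_samples
    alpha = config.alpha_detection
    pvals = np.where(probe_state, u * alpha, alpha + u * (1.0 - alpha))
    probe_df = pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, config.n_samples),
            "gene_id": np.repeat(genes[probe_gene_idx], config.n_samples),
            "context_id": np.tile(samples, n_probe),
            "detection_p": pvals.ravel(),
        }
    )
    level_hi = rng.lognormal(math.log(500.0), 0.8, (config.n_samples, config.n_genes))
    level_lo = rng.lognormal(math.log(50.0), 0.8, (config.n_samples, config.n_genes))
    levels = np.where(state, level_hi, level_lo)
    levels[:, ~has_data] = np.nan
    levels_df = pd.DataFrame(levels, index=samples, columns=genes)
    expression = call_expression(
        probe_df, alpha=alpha, levels=levels_df, genes=genes, contexts=samples
    )

    # --- healthy-tissue panel (breadth analyses) --------------------------
    tissues = [f"T{i:03d}" for i in range(config.n_tissues)]
    kind = rng.random(config.n_genes)
    q = np.where(kind < 0.2, rng.uniform(0.97, 1.0, config.n_genes),
                 np.where(kind < 0.5, rng.uniform(0.0, 0.2, config.n_genes),
                          rng.uniform(0.2, 0.9, config.n_genes)))
    tstate = rng.random((config.n_tissues, config.n_genes)) < q
    tcalls = np.where(tstate, EXPRESSED, NOT_EXPRESSED).astype(object)
    tcalls[:, ~has_data] = NO_DATA
    tissue_expression = ExpressionCallMatrix(
        calls=pd.DataFrame(tcalls, index=tissues, columns=genes)
    )

    # --- interaction network ----------------------------------------------
    n_net = round(config.network_fraction * config.n_genes)
    must = sorted(known | {g for gs in planted.values() for g in gs})
    if n_net < len(must):
        n_net = len(must)
    others = np.array([g for g in genes if g not in set(must)])
    extra = rng.choice(others, size=n_net - len(must), replace=False)
    members = np.array(must + sorted(extra))
    rng.shuffle(members)
    base = generate_network(n_net, config.network_attachment, seed=int(rng.integers(2**31)))
    network = nx.relabel_nodes(base, dict(enumerate(members)))

    # --- annotations -------------------------------------------------------
    driver_genes = {g for gs in planted.values() for g in gs}
    mutated_genes = {m.gene_id for m in mutations}
    epochs = np.array(ORIGIN_EPOCHS)
    gene_records: Dict[str, GeneRecord] = {}
    for j, g in enumerate(genes):
        g = str(g)
        if g in driver_genes:
            origin, dup = "metazoa", "singleton"
        elif g in known:
            origin = str(rng.choice(["ancient", "metazoa"], p=[0.6, 0.4]))
            dup = str(rng.choice(["singleton", "duplicated"], p=[0.7, 0.3]))
        else:
            origin = None if rng.random() < 0.05 else str(rng.choice(epochs))
            dup = None if rng.random() < 0.05 else str(
                rng.choice(["singleton", "duplicated"])
            )
        if g in known:
            gene_class = "known"
        elif g in mutated_genes:
            gene_class = "other_mutated"
        else:
            gene_class = "non_mutated"
        n_types = int(min(20, rng.poisson(1.0 + 3.0 * lengths[j] / 4450.0)))
        gene_records[g] = GeneRecord(
            gene_id=g,
            symbol=g,
            coding_length_bp=int(lengths[j]),
            gene_class=gene_class,
            origin_epoch=origin,
            duplicability=dup,
            n_cancer_types_mutated=n_types,
        )

    # --- shRNA screen ------------------------------------------------------
    screen, suppressors = _generate_screen(config, rng, genes, known)

    bundle = CohortBundle(
        genes=gene_records,
        mutations=mutations,
        expression=expression,
        network=network,
        known_cancer_set=frozenset(known),
        sample_to_cancer_type={s: config.cancer_type for s in samples},
        screen=screen,
        tissue_expression=tissue_expression,
    )
    truth = GroundTruth(drivers=dict(sorted(planted.items())), suppressors=suppressors)
    return bundle, truth


def _generate_screen(config, rng, genes, known):
    non_known = np.array([g for g in genes if g not in known])
    if config.n_suppressors > len(non_known):
        raise ValidationError("more screen suppressors than non-known genes")
    suppressors = frozenset(
        str(g) for g in rng.choice(non_known, config.n_suppressors, replace=False)
    )
    k = config.screen_probes_per_gene
    probe_ids = [f"{g}_sh{j}" for g in genes for j in range(k)]
    probe_to_gene = {p: p.rsplit("_sh", 1)[0] for p in probe_ids}
    is_supp = np.repeat(np.array([g in suppressors for g in genes]), k)

    conditions, groups = [], {}
    for h in range(config.n_cell_lines):
        line = f"CL{h:02d}"
        groups[line] = [f"{line}_r{j}" for j in range(config.replicates_per_line)]
        conditions.extend(groups[line])
    groups["DNA"] = [f"DNA_r{j}" for j in range(config.pool_replicates)]
    conditions.extend(groups["DNA"])

    base = rng.normal(6.0, 1.0, size=len(probe_ids))
    n_line_cond = config.n_cell_lines * config.replicates_per_line
    delta = np.zeros((len(probe_ids), len(conditions)))
    delta[is_supp, :n_line_cond] = config.suppressor_effect
    noise = rng.normal(0.0, config.screen_noise_sd, size=delta.shape)
    scores = np.exp2(base[:, None] + delta + noise)
    screen = ShrnaScreen(
        scores=pd.DataFrame(scores, index=probe_ids, columns=conditions),
        probe_to_gene=probe_to_gene,
        groups=groups,
        reference_group="DNA",
    )
    return screen, suppressors


def write_cohort(bundle: CohortBundle, truth: GroundTruth, outdir) -> None:
    """Write every input format plus truth.tsv, for CLI round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_mutation_table(bundle.mutations, outdir / "mutations.tsv")
    dio.write_gene_table(bundle.genes, outdir / "genes.tsv")
    dio.write_network(bundle.network, outdir / "network.tsv")
    dio.write_call_matrix(
        bundle.expression, outdir / "expression_calls.tsv", outdir / "expression_levels.tsv"
    )
    dio.write_known_set(bundle.known_cancer_set, outdir / "known_genes.txt")
    if bundle.tissue_expression is not None:
        dio.write_call_matrix(bundle.tissue_expression, outdir / "tissue_calls.tsv")
    if bundle.screen is not None:
        dio.write_gct(bundle.screen, outdir / "screen.gct")
        cond_map = {
            c: g for g, conds in bundle.screen.groups.items() for c in conds
        }
        dio.write_group_map(cond_map, outdir / "screen_groups.tsv")
    rows = [
        {"sample_id": s, "gene_id": g}
        for s in sorted(truth.drivers)
        for g in sorted(truth.drivers[s])
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene_id"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": sorted(truth.suppressors)}).to_csv(
        outdir / "suppressors.tsv", sep="\t", index=False
    )
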