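"""Gene-silencing effect scores from pooled shRNA dropout screens.

A screen measures the abundance of every short-hairpin probe in the final
cell population of each cell line (several infection replicates per line)
and in the initial DNA pool that seeded the infections. Silencing a
tumour suppressor increases proliferation, so its hairpins are enriched
relative to the pool; the per-probe readout is

    log2ratio(h, i) = log2( mean_j score(h, i, j) / mean_k score(DNA, i, k) )

for probe i in cell line h, averaging over cell-line replicates j and
pool replicates k. Genes typically carry ~5 probes; the gene-level effect
collapses to the top-scoring (maximum) probe ratio to limit false
negatives from inefficient hairpins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("driverlens")


@dataclass
class ShrnaScreen:
    """Probe x condition abundance matrix with replicate grouping.

    ``groups`` maps a group id (cell line or the reference pool) to its
    replicate condition columns; ``reference_group`` names the initial
    DNA pool used as denominator.
    """

    scores: pd.DataFrame
    probe_to_gene: Dict[str, Optional[str]]
    groups: Dict[str, List[str]] = field(default_factory=dict)
    reference_group: Optional[str] = None

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for group, conditions in self.groups.items():
            if len(conditions) < 1:
                raise ValidationError(f"group {group!r} has no replicates")
            for cond in conditions:
                if cond in seen:
                    raise ValidationError(
                        f"condition {cond!r} assigned to both "
                        f"{seen[cond]!r} and {group!r}"
                    )
                if cond not in self.scores.columns:
                    raise ValidationError(f"unknown condition {cond!r}")
                seen[cond] = group

    @property
    def cell_lines(self) -> List[str]:
        return sorted(g for g in self.groups if g != self.reference_group)

    def probes_for_gene(self, gene_id: str) -> List[str]:
        index = getattr(self, "_gene_index", None)
        if index is None:
            index = {}
            for p, g in self.probe_to_gene.items():
                if g is not None:
                    index.setdefault(g, []).append(p)
            for probes in index.values():
                probes.sort()
            object.__setattr__(self, "_gene_index", index)
        return list(index.get(gene_id, []))


def assign_groups(
    screen: ShrnaScreen, condition_to_group: Dict[str, str], reference_group: str
) -> ShrnaScreen:
    """Attach a replicate-group map (condition_id -> group_id) to a screen."""
    groups: Dict[str, List[str]] = {}
    for cond, group in sorted(condition_to_group.items()):
        groups.setdefault(group, []).append(cond)
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} not in map")
    return ShrnaScreen(
        scores=screen.scores,
        probe_to_gene=screen.probe_to_gene,
        groups=groups,
        reference_group=reference_group,
    )


@dataclass(frozen=True)
class GeneSilencingEffect:
    gene_id: str
    cell_line: str
    log2ratio: Optional[float]
    n_probes: int


def probe_log2ratio(screen: ShrnaScreen, cell_line: str, probe: str) -> Optional[float]:
    """log2 ratio of replicate-mean abundances, cell line over DNA pool.

    Returns None (missing) when either replicate mean is non-positive:
    a log ratio of normalized scores is undefined there, and clamping
    would bias the downstream max-collapse.
    """
    if probe not in screen.scores.index:
        raise ValidationError(f"unknown probe {probe!r}")
    if cell_line not in screen.groups:
        raise ValidationError(f"unknown cell line {cell_line!r}")
    if screen.reference_group is None:
        raise ValidationError("screen has no reference group")
    num = float(np.mean(screen.scores.loc[probe, screen.groups[cell_line]]))
    den = float(
        np.mean(screen.scores.loc[probe, screen.groups[screen.reference_group]])
    )
    if num <= 0.0 or den <= 0.0:
        return None
    return math.log2(num / den)


def gene_effect(
    screen: ShrnaScreen, cell_line: str, gene_id: str, direction: str = "max"
) -> GeneSilencingEffect:
    """Collapse a gene's probe ratios to its representative effect.

    ``direction="max"`` keeps the top-scoring hairpin (proliferation
    readout); ``"min"`` supports depletion analyses.
    """
    if direction not in ("max", "min"):
        raise ValidationError(f"direction must be 'max' or 'min', got {direction!r}")
    probes = screen.probes_for_gene(gene_id)
    if not probes:
        raise ValidationError(f"gene {gene_id!r} has no probes in the screen")
    ratios = [probe_log2ratio(screen, cell_line, p) for p in probes]
    valid = [r for r in ratios if r is not None]
    if not valid:
        return GeneSilencingEffect(gene_id, cell_line, None, len(probes))
    pick = max(valid) if direction == "max" else min(valid)
    return GeneSilencingEffect(gene_id, cell_line, pick, len(probes))


def gene_effect_table(
    screen: ShrnaScreen, genes=None, direction: str = "max"
) -> pd.DataFrame:
    """Long table of gene x cell-line silencing effects."""
    if genes is None:
        genes = sorted({g for g in screen.probe_to_gene.values() if g is not None})
    rows = []
    for gene in genes:
        for line in screen.cell_lines:
            eff = gene_effect(screen, line, gene, direction=direction)
            rows.append(
                {
                    "gene_id": gene,
                    "cell_line": line,
                    "log2ratio_shrna": eff.log2ratio,
                    "n_probes": eff.n_probes,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "cell_line", "log2ratio_shrna", "n_probes"])


def proliferation_count(
    screen: ShrnaScreen, gene_id: str, cell_lines, threshold: float = 0.0
) -> dict:
    """Count cell lines where silencing the gene increased proliferation.

    Lines with a missing effect are excluded from the count and listed.
    """
    n = 0
    missing = []
    for line in cell_lines:
        eff = gene_effect(screen, line, gene_id)
        if eff.log2ratio is None:
            missing.append(line)
        elif eff.log2ratio > threshold:
            n += 1
    return {"gene_id": gene_id, "n_increased": n, "missing_lines": missing}


def compare_silencing_groups(effects_a, effects_b) -> dict:
    """Two-sided rank-sum comparison of two effect distributions.

    Shapiro-Wilk p-values are reported for transparency only; the test
    choice never switches on them. Exact rank-sum null is used when no
    ties are present, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray([x for x in effects_a if x is not None], dtype=float)
    b = np.asarray([x for x in effects_b if x is not None], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    method = "exact" if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return {
        "wilcoxon_p": float(res.pvalue),
        "shapiro_p_a": float(stats.shapiro(a).pvalue),
        "shapiro_p_b": float(stats.shapiro(b).pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
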