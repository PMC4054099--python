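"""Core in-memory containers for a tumour cohort.

A cohort bundles four layers of evidence about mutated genes:

* static per-gene annotation (coding length, cancer class, evolutionary
  origin, duplicability, pan-cancer recurrence),
* somatic non-synonymous mutation events with damage-predictor scores,
* ternary expression calls (expressed / not expressed / no data) per
  context, where a context is either a healthy tissue or a tumour sample,
* an undirected protein-protein interaction network.

Gene identifiers are opaque strings matched case-sensitively; no alias
resolution is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("driverlens")

MUTATION_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "synonymous", "other"}
)
#: Variant classes treated as protein-truncating, hence damaging by class.
TRUNCATING_CLASSES = frozenset({"frameshift", "nonsense", "splice_site"})

GENE_CLASSES = frozenset({"known", "candidate", "other_mutated", "non_mutated"})

#: Phylostratigraphic epochs ordered from oldest to youngest.
ORIGIN_EPOCHS = ("ancient", "eukaryota", "metazoa", "vertebrata", "mammalia", "recent")

DUPLICABILITY = frozenset({"singleton", "duplicated"})

EXPRESSED = "expressed"
NOT_EXPRESSED = "not_expressed"
NO_DATA = "no_data"
CALL_VALUES = (EXPRESSED, NOT_EXPRESSED, NO_DATA)

MUTATION_TASTER_CALLS = frozenset({"disease_causing", "polymorphism"})


def _check_unit_interval(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class GeneRecord:
    """Static annotation of one gene.

    ``coding_length_bp`` is the coding portion of the longest isoform.
    ``n_cancer_types_mutated`` counts the cancer types of a pan-cancer
    recurrence reference in which the gene carries non-synonymous
    mutations; it feeds the long-gene correction of the driver cascade.
    """

    gene_id: str
    symbol: str = ""
    coding_length_bp: int = 1
    gene_class: str = "other_mutated"
    origin_epoch: Optional[str] = None
    duplicability: Optional[str] = None
    n_cancer_types_mutated: int = 0

    def __post_init__(self) -> None:
        if self.coding_length_bp < 1:
            raise ValidationError(
                f"coding_length_bp must be >= 1 for {self.gene_id}, "
                f"got {self.coding_length_bp}"
            )
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"unknown gene_class {self.gene_class!r}")
        if self.origin_epoch is not None and self.origin_epoch not in ORIGIN_EPOCHS:
            raise ValidationError(f"unknown origin_epoch {self.origin_epoch!r}")
        if self.duplicability is not None and self.duplicability not in DUPLICABILITY:
            raise ValidationError(f"unknown duplicability {self.duplicability!r}")
        if self.n_cancer_types_mutated < 0:
            raise ValidationError("n_cancer_types_mutated must be >= 0")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic non-synonymous event in one sample.

    Predictor scores are damage-oriented in [0, 1] (higher = more
    damaging); missing scores are legal and count as negative votes in
    the 2-of-3 consensus.
    """

    sample_id: str
    gene_id: str
    mutation_class: str
    sift_damage_score: Optional[float] = None
    polyphen_score: Optional[float] = None
    mutation_taster_call: Optional[str] = None
    conservation_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValidationError(f"unknown mutation_class {self.mutation_class!r}")
        _check_unit_interval("sift_damage_score", self.sift_damage_score)
        _check_unit_interval("polyphen_score", self.polyphen_score)
        _check_unit_interval("conservation_score", self.conservation_score)
        if (
            self.mutation_taster_call is not None
            and self.mutation_taster_call not in MUTATION_TASTER_CALLS
        ):
            raise ValidationError(
                f"unknown mutation_taster_call {self.mutation_taster_call!r}"
            )


@dataclass
class ExpressionCallMatrix:
    """Ternary expression calls, context x gene.

    ``calls`` is a DataFrame indexed by context_id with gene_id columns
    and values in ``{"expressed", "not_expressed", "no_data"}``. ``level``
    optionally holds an expression level on the same axes; it is only
    meaningful where the call is not ``no_data``.
    """

    calls: pd.DataFrame
    level: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        bad = set(pd.unique(self.calls.values.ravel())) - set(CALL_VALUES)
        if bad:
            raise ValidationError(f"invalid call values {sorted(bad)!r}")
        if self.level is not None:
            self.level = self.level.reindex(
                index=self.calls.index, columns=self.calls.columns
            )

    @property
    def contexts(self) -> list:
        return list(self.calls.index)

    @property
    def genes(self) -> list:
        return list(self.calls.columns)

    def call(self, context: str, gene: str) -> str:
        """Call for one (context, gene) pair; absent pairs are no_data."""
        if context not in self.calls.index or gene not in self.calls.columns:
            return NO_DATA
        return self.calls.at[context, gene]

    def genes_with_data(self, context: str) -> set:
        row = self.calls.loc[context]
        return set(row.index[row != NO_DATA])

    def expressed_genes(self, context: str) -> set:
        row = self.calls.loc[context]
        return set(row.index[row == EXPRESSED])

    def breadth(self) -> pd.DataFrame:
        """Per gene: number of contexts expressed and with data."""
        expressed = (self.calls == EXPRESSED).sum(axis=0)
        with_data = (self.calls != NO_DATA).sum(axis=0)
        return pd.DataFrame(
            {"n_expressed": expressed, "n_with_data": with_data}
        ).rename_axis("gene_id")

    def highly_expressed_genes(self, context: str) -> set:
        """Genes whose level exceeds the context median over genes with data."""
        if self.level is None:
            raise ValidationError("no expression levels available")
        row = self.calls.loc[context]
        has_data = row != NO_DATA
        levels = self.level.loc[context][has_data].dropna()
        if levels.empty:
            return set()
        median = levels.median()
        return set(levels.index[levels > median])


@dataclass
class CohortBundle:
    """All inputs of the driver cascade for one cohort."""

    genes: Mapping[str, GeneRecord]
    mutations: list
    expression: ExpressionCallMatrix
    network: nx.Graph
    known_cancer_set: frozenset
    sample_to_cancer_type: Mapping[str, str]
    screen: Optional[object] = None
    tissue_expression: Optional[ExpressionCallMatrix] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        unannotated = sorted(
            {m.gene_id for m in self.mutations} - set(self.genes.keys())
        )
        if unannotated:
            msg = f"{len(unannotated)} mutated genes lack annotation"
            self.warnings.append(msg)
            logger.warning(msg)
        orphans = set(self.expression.contexts) - self.sample_ids()
        # tissue panels legitimately use non-sample contexts; warn only when
        # the matrix looks sample-indexed (some overlap exists)
        if orphans and (set(self.expression.contexts) & self.sample_ids()):
            msg = f"{len(orphans)} expression contexts have no mutations; ignored"
            self.warnings.append(msg)
            logger.warning(msg)

    def sample_ids(self) -> set:
        return {m.sample_id for m in self.mutations}

    def mutations_by_sample(self) -> dict:
        out: dict = {}
        for m in self.mutations:
            out.setdefault(m.sample_id, []).append(m)
        return out


def report_to_json(obj, **kwargs) -> str:
    """Deterministic JSON serialization used by report writers."""
    return json.dumps(obj, sort_keys=True, indent=2, default=str, **kwargs)
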