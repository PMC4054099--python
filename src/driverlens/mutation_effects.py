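"""Damaging-mutation consensus, recurrence counts and the length trend.

Truncating events (frameshift, nonsense, splice-site) are damaging by
class. Missense events are damaging when at least two of three
predictors agree: SIFT damage score > 0.95, PolyPhen score > 0.9, or a
MutationTaster "disease causing" label. Missing predictor scores count
as negative votes, keeping the 2-of-3 denominator fixed. Recurrence is
counted with distinct-sample semantics, and the dependence of
recurrence on coding length is summarized by an OLS fit of the
per-recurrence-level median length — long genes accumulate passenger
mutations roughly in proportion to their coding footprint, which is the
bias the driver cascade's length filter corrects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .records import MutationRecord, TRUNCATING_CLASSES


@dataclass(frozen=True)
class DamagingCall:
    is_damaging: bool
    basis: str  # truncating_class | missense_consensus | not_damaging
    votes: int


def damaging_call(
    mut: MutationRecord, sift_thr: float = 0.95, polyphen_thr: float = 0.9
) -> DamagingCall:
    """Consensus damage call for one mutation.

    Thresholds are strict (a SIFT damage score of exactly 0.95 votes
    false). Synonymous and unclassified events are never damaging.
    """
    if not (0.0 < sift_thr < 1.0) or not (0.0 < polyphen_thr < 1.0):
        raise ValidationError("thresholds must lie in (0, 1)")
    if mut.mutation_class in TRUNCATING_CLASSES:
        return DamagingCall(True, "truncating_class", 0)
    if mut.mutation_class != "missense":
        return DamagingCall(False, "not_damaging", 0)
    votes = 0
    if mut.sift_damage_score is not None and mut.sift_damage_score > sift_thr:
        votes += 1
    if mut.polyphen_score is not None and mut.polyphen_score > polyphen_thr:
        votes += 1
    if mut.mutation_taster_call == "disease_causing":
        votes += 1
    if votes >= 2:
        return DamagingCall(True, "missense_consensus", votes)
    return DamagingCall(False, "not_damaging", votes)


def recurrence_counts(
    mutations: Iterable[MutationRecord], sample_to_cancer_type: Mapping[str, str]
) -> pd.DataFrame:
    """Per gene: distinct cancer types and distinct samples mutated.

    A gene hit twice in one sample counts once for that sample; row
    order is irrelevant. Raises when a sample lacks a cancer-type
    mapping.
    """
    types: Dict[str, set] = {}
    samples: Dict[str, set] = {}
    for m in mutations:
        if m.sample_id not in sample_to_cancer_type:
            raise ValidationError(f"sample {m.sample_id!r} has no cancer-type mapping")
        types.setdefault(m.gene_id, set()).add(sample_to_cancer_type[m.sample_id])
        samples.setdefault(m.gene_id, set()).add(m.sample_id)
    rows = [
        {
            "gene_id": gene,
            "n_cancer_types": len(types[gene]),
            "n_samples": len(samples[gene]),
        }
        for gene in sorted(types)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_cancer_types", "n_samples"]).set_index(
        "gene_id"
    )


@dataclass(frozen=True)
class LengthTrend:
    slope: float  # bp per recurrence unit
    r_squared: float
    n_levels: int


def length_recurrence_trend(
    lengths: Mapping[str, int],
    recurrence: Mapping[str, int],
    fit_all_points: bool = False,
) -> LengthTrend:
    """OLS trend of coding length against mutation recurrence.

    By default each recurrence level contributes its median coding
    length (robust per-level summary); ``fit_all_points=True`` fits
    every gene instead. Requires at least 3 distinct recurrence levels.
    """
    genes = sorted(set(lengths) & set(recurrence))
    if not genes:
        raise ValidationError("no genes with both length and recurrence")
    x = np.array([recurrence[g] for g in genes], dtype=float)
    y = np.array([lengths[g] for g in genes], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need at least 3 distinct recurrence levels")
    if not fit_all_points:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].median()
        x, y = df.index.to_numpy(), df.to_numpy()
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return LengthTrend(slope=float(res.slope), r_squared=r2, n_levels=len(np.unique(x)))


def damaging_summary_table(
    mutations: Iterable[MutationRecord],
    sample_to_cancer_type: Mapping[str, str],
    sift_thr: float = 0.95,
    polyphen_thr: float = 0.9,
) -> pd.DataFrame:
    """Per-gene recurrence plus damaging-mutation count (TSV-ready)."""
    mutations = list(mutations)
    rec = recurrence_counts(mutations, sample_to_cancer_type)
    damaging: Dict[str, int] = {}
    for m in mutations:
        call = damaging_call(m, sift_thr=sift_thr, polyphen_thr=polyphen_thr)
        damaging[m.gene_id] = damaging.get(m.gene_id, 0) + int(call.is_damaging)
    rec["n_damaging_mutations"] = pd.Series(damaging).reindex(rec.index).fillna(0).astype(int)
    return rec
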