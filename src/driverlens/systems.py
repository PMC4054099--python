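"""Systems-level gene properties used to prioritize putative drivers.

Known cancer genes tend to encode central hubs of the protein
interaction network, to interact directly with other cancer proteins,
to have appeared early in evolution or with metazoans/vertebrates, and
to remain single-copy in the genome. A mutated gene sharing enough of
these four properties "resembles" a cancer gene and passes the final
stage of the driver cascade.

Betweenness is the unnormalized, endpoints-excluded shortest-path count
(the convention under which the 25% hub cut on a ~13,500-protein network
sits near raw values of degree 14 and betweenness ~9,200); hub cuts are
empirical quantiles with the linear-interpolation convention, and hub
membership requires strictly exceeding both cuts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Set

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import GeneRecord

logger = logging.getLogger("driverlens")

#: Epochs treated as cancer-like origins: early evolution plus the
#: metazoan and vertebrate radiations.
DEFAULT_CANCER_LIKE_EPOCHS = frozenset({"ancient", "metazoa", "vertebrata"})


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalized betweenness for every network node.

    Betweenness of v sums, over unordered node pairs {s, t} with
    s != v != t, the fraction of shortest s-t paths through v;
    disconnected pairs contribute zero.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=False)
    nodes = sorted(net.nodes())
    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )


@dataclass(frozen=True)
class HubThresholds:
    degree_thr: float
    betweenness_thr: float
    quantile: float


def hub_thresholds(table: pd.DataFrame, quantile: float = 0.75) -> HubThresholds:
    """Empirical quantile cuts over all network nodes (linear interpolation)."""
    if not (0.0 < quantile < 1.0):
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    if len(table) == 0:
        raise ValidationError("empty centrality table")
    return HubThresholds(
        degree_thr=float(np.quantile(table["degree"], quantile)),
        betweenness_thr=float(np.quantile(table["betweenness"], quantile)),
        quantile=quantile,
    )


def is_central_hub(
    degree: float, betweenness: float, thresholds: HubThresholds
) -> bool:
    """Hub = strictly above both the degree and the betweenness cut."""
    return degree > thresholds.degree_thr and betweenness > thresholds.betweenness_thr


def cancer_interactor(net: nx.Graph, gene: str, known_set: Set[str]) -> bool:
    """True iff the gene has a direct neighbour in the known cancer set.

    The gene's own membership is ignored; absence from the network is
    absence of evidence (False with a warning), not an error.
    """
    if gene not in net:
        logger.warning("gene %s absent from network; not a cancer interactor", gene)
        return False
    return any(nb in known_set for nb in net.neighbors(gene))


@dataclass(frozen=True)
class SystemsProfile:
    gene_id: str
    central_hub: bool
    cancer_interactor: bool
    cancer_like_origin: bool
    singleton: bool

    @property
    def n_true(self) -> int:
        return sum(
            (self.central_hub, self.cancer_interactor, self.cancer_like_origin, self.singleton)
        )


def systems_profile(
    gene: GeneRecord,
    net: nx.Graph,
    thresholds: HubThresholds,
    known_set: Set[str],
    centralities: Optional[pd.DataFrame] = None,
    cancer_like_epochs: Set[str] = DEFAULT_CANCER_LIKE_EPOCHS,
) -> SystemsProfile:
    """Evaluate the four cancer-gene-like properties for one gene.

    Missing origin or duplicability annotation makes the corresponding
    flag False; genes absent from the network are non-hubs and
    non-interactors.
    """
    hub = False
    if gene.gene_id in net:
        if centralities is not None and gene.gene_id in centralities.index:
            deg = centralities.at[gene.gene_id, "degree"]
            btw = centralities.at[gene.gene_id, "betweenness"]
        else:
            deg = net.degree(gene.gene_id)
            btw = nx.betweenness_centrality(net, normalized=False)[gene.gene_id]
        hub = is_central_hub(deg, btw, thresholds)
    return SystemsProfile(
        gene_id=gene.gene_id,
        central_hub=hub,
        cancer_interactor=cancer_interactor(net, gene.gene_id, known_set),
        cancer_like_origin=gene.origin_epoch in cancer_like_epochs,
        singleton=gene.duplicability == "singleton",
    )


def passes_systems_filter(profile: SystemsProfile, min_true: int = 2) -> bool:
    """Pass iff at least ``min_true`` of the four properties hold.

    The combination rule is deliberately a knob: requiring all four
    would exclude most genuine drivers (few are hubs), requiring none
    disables the stage.
    """
    if not (0 <= min_true <= 4):
        raise ValidationError(f"min_true must be in [0, 4], got {min_true}")
    return profile.n_true >= min_true


def systems_table(
    genes,
    net: nx.Graph,
    thresholds: HubThresholds,
    known_set: Set[str],
    centralities: pd.DataFrame,
    cancer_like_epochs: Set[str] = DEFAULT_CANCER_LIKE_EPOCHS,
) -> pd.DataFrame:
    """Per-gene systems flags (TSV-ready)."""
    rows = []
    for gene in genes:
        prof = systems_profile(
            gene, net, thresholds, known_set, centralities, cancer_like_epochs
        )
        in_net = gene.gene_id in net
        rows.append(
            {
                "gene_id": gene.gene_id,
                "degree": centralities.at[gene.gene_id, "degree"] if in_net else 0,
                "betweenness": centralities.at[gene.gene_id, "betweenness"] if in_net else 0.0,
                "central_hub": prof.central_hub,
                "cancer_interactor": prof.cancer_interactor,
                "cancer_like_origin": prof.cancer_like_origin,
                "singleton": prof.singleton,
                "n_true": prof.n_true,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
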