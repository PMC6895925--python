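"""Network annotation: GWAS node priors, edgetic edge damage, seed selection.

This module turns the two upstream data products into a fully weighted
network:

* A gene-score table (gene -> GWAS p-value, as produced by SNP-to-gene
  aggregation tools such as Pascal).  Each scored gene i receives the raw
  node weight -log10(P_i); raw weights are min-max normalized to [0, 1] to
  form the prior vector Y used by propagation, with unscored genes at 0.
* Variant-level edgetic annotations (as produced by structure-based effect
  predictors such as the SNP-IN tool).  A variant's effect on a specific
  interaction is classified from the binding free-energy change ddG
  (kcal/mol): beneficial below -0.5, detrimental at or above 0.5, neutral in
  between.  Each interaction i-j is weighted with the total count of
  detrimental variants on either endpoint gene targeting that interaction;
  beneficial and neutral variants contribute nothing.

Raw damage counts are mapped into (0, 1) by a logistic transform before
propagation, so that an undamaged-but-present interaction still conducts
signal (weight 0.5) while heavily damaged interactions approach 1.

Seed genes are the scored genes significant after Bonferroni correction over
the score table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeticEffect",
    "EdgeticAnnotation",
    "GeneScoreTable",
    "NodePriors",
    "WeightedNetwork",
    "classify_edgetic_effect",
    "select_seeds",
    "compute_node_priors",
    "compute_edge_damage",
    "transform_edge_weights",
    "build_weighted_network",
    "read_annotations",
    "write_annotations",
]

#: ddG thresholds (kcal/mol) separating beneficial / neutral / detrimental.
DDG_BENEFICIAL_BELOW = -0.5
DDG_DETRIMENTAL_AT = 0.5

#: Smallest p-value accepted before clamping (guards -log10 against P == 0).
DEFAULT_P_FLOOR = 1e-300


class EdgeticEffect(str, Enum):
    """Effect of a variant on a specific protein-protein interaction."""

    BENEFICIAL = "beneficial"
    NEUTRAL = "neutral"
    DETRIMENTAL = "detrimental"


def classify_edgetic_effect(ddg: float) -> EdgeticEffect:
    """Classify a binding free-energy change (kcal/mol) into an edgetic class.

    beneficial iff ddg < -0.5; neutral iff -0.5 <= ddg < 0.5; detrimental iff
    ddg >= 0.5 (both boundaries follow the half-open convention, so -0.5 is
    neutral and 0.5 is detrimental).
    """
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValueError(f"ddG must be finite, got {ddg!r}")
    if ddg < DDG_BENEFICIAL_BELOW:
        return EdgeticEffect.BENEFICIAL
    if ddg < DDG_DETRIMENTAL_AT:
        return EdgeticEffect.NEUTRAL
    return EdgeticEffect.DETRIMENTAL


@dataclass
class EdgeticAnnotation:
    """One variant's predicted effect on one interaction.

    At least one of ``ddg`` / ``effect_class`` must be present.  When both
    are present, ddg wins (it is the primary upstream output) and a mismatch
    with the stated class is logged.
    """

    variant_id: str
    gene: str
    partner: str
    ddg: float | None = None
    effect_class: EdgeticEffect | None = None

    def __post_init__(self) -> None:
        if isinstance(self.effect_class, str):
            self.effect_class = EdgeticEffect(self.effect_class.lower())
        if self.ddg is None and self.effect_class is None:
            raise ValueError(
                f"annotation {self.variant_id!r}: needs ddg or effect_class"
            )
        if self.ddg is not None:
            self.ddg = float(self.ddg)

    def resolved_class(self) -> EdgeticEffect:
        """Effect class, derived from ddg when available."""
        if self.ddg is not None:
            cls = classify_edgetic_effect(self.ddg)
            if self.effect_class is not None and self.effect_class != cls:
                logger.warning(
                    "annotation %s: stated class %s disagrees with ddg=%.3f (%s); using ddg",
                    self.variant_id, self.effect_class.value, self.ddg, cls.value,
                )
            return cls
        assert self.effect_class is not None
        return self.effect_class


def read_annotations(path: str | Path) -> list[EdgeticAnnotation]:
    """Read a variant-level annotation TSV.

    Columns: variant_id, gene, partner, ddg (float, may be empty),
    effect_class (may be empty).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"variant_id", "gene", "partner"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[EdgeticAnnotation] = []
    for row in df.itertuples(index=False):
        ddg = getattr(row, "ddg", None)
        if ddg is not None and (isinstance(ddg, float) and math.isnan(ddg)):
            ddg = None
        cls = getattr(row, "effect_class", None)
        if cls is not None and (not isinstance(cls, str) or not cls.strip()):
            cls = None
        out.append(
            EdgeticAnnotation(
                variant_id=str(row.variant_id),
                gene=str(row.gene),
                partner=str(row.partner),
                ddg=ddg,
                effect_class=cls,
            )
        )
    return out


def write_annotations(annotations: Sequence[EdgeticAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "variant_id": a.variant_id,
                "gene": a.gene,
                "partner": a.partner,
                "ddg": "" if a.ddg is None else repr(a.ddg),
                "effect_class": "" if a.effect_class is None else a.effect_class.value,
            }
        )
    pd.DataFrame(rows, columns=["variant_id", "gene", "partner", "ddg", "effect_class"]).to_csv(
        path, sep="\t", index=False
    )


class GeneScoreTable:
    """Per-gene GWAS p-values with derived -log10 weights.

    P-values must lie in (0, 1]; values of exactly 0 (or below the floor)
    are clamped to ``p_floor`` with a logged count, since -log10(0) is
    undefined.  Raw weights are -log10(P); ``p_min`` / ``p_max`` are the
    extremes of the raw weights over the scored genes and are retained so
    propagated scores can later be mapped back to the raw -log10 scale.
    """

    def __init__(self, pvalues: Mapping[str, float], p_floor: float = DEFAULT_P_FLOOR):
        if not pvalues:
            raise ValueError("gene score table is empty")
        self.p_floor = float(p_floor)
        self.pvalues: dict[str, float] = {}
        n_clamped = 0
        for gene, p in pvalues.items():
            p = float(p)
            if not math.isfinite(p) or p < 0.0 or p > 1.0:
                raise ValueError(f"gene {gene!r}: p-value {p!r} outside [0, 1]")
            if p < self.p_floor:
                p = self.p_floor
                n_clamped += 1
            self.pvalues[str(gene)] = p
        if n_clamped:
            logger.warning("clamped %d p-value(s) to floor %.3g", n_clamped, self.p_floor)
        self.n_clamped = n_clamped

    @classmethod
    def from_tsv(cls, path: str | Path, p_floor: float = DEFAULT_P_FLOOR) -> "GeneScoreTable":
        """Read a gene-score TSV with required header columns gene, p_value."""
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if not {"gene", "p_value"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'gene' and 'p_value'")
        return cls(dict(zip(df["gene"].astype(str), df["p_value"].astype(float))), p_floor=p_floor)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"gene": list(self.pvalues), "p_value": [repr(p) for p in self.pvalues.values()]}
        )
        df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.pvalues)

    def __contains__(self, gene: str) -> bool:
        return gene in self.pvalues

    def raw_weights(self) -> dict[str, float]:
        """-log10(P_i) per scored gene (dimensionless, >= 0)."""
        return {g: -math.log10(p) for g, p in self.pvalues.items()}


def select_seeds(scores: GeneScoreTable, family_alpha: float = 0.05) -> set[str]:
    """Bonferroni-corrected seed selection.

    Returns genes with P_i <= family_alpha / m, where m is the number of
    genes in the score table (the family actually tested).
    """
    if not 0.0 < family_alpha < 1.0:
        raise ValueError(f"family_alpha must be in (0, 1), got {family_alpha}")
    m = len(scores)
    threshold = family_alpha / m
    return {g for g, p in scores.pvalues.items() if p <= threshold}


@dataclass
class NodePriors:
    """Normalized node-prior vector Y aligned to a node ordering.

    ``p_min`` / ``p_max`` are the raw -log10(P) extremes over the score
    table, kept for the later inverse (de-normalization) map.
    """

    nodes: list[str]
    values: np.ndarray  # Y in [0, 1]^|V|
    p_min: float
    p_max: float
    n_unscored: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.values.tolist()))


def compute_node_priors(scores: GeneScoreTable, net: Interactome) -> NodePriors:
    """Min-max-normalized -log10(P) priors over the interactome's nodes.

    Y_i = (raw_i - p_min) / (p_max - p_min) for scored genes; genes absent
    from the score table get Y_i = 0.  If all raw weights are equal the
    normalization is degenerate (0/0); every scored gene then receives the
    maximal prior 1.0 so that scored genes still outrank unscored ones.
    """
    raw = scores.raw_weights()
    p_min = min(raw.values())
    p_max = max(raw.values())
    nodes = net.sorted_nodes()
    y = np.zeros(len(nodes))
    span = p_max - p_min
    n_unscored = 0
    for i, gene in enumerate(nodes):
        if gene in raw:
            y[i] = (raw[gene] - p_min) / span if span > 0 else 1.0
        else:
            n_unscored += 1
    return NodePriors(nodes=nodes, values=y, p_min=p_min, p_max=p_max, n_unscored=n_unscored)


def compute_edge_damage(
    annotations: Iterable[EdgeticAnnotation],
    net: Interactome,
    nodes: Sequence[str] | None = None,
) -> tuple[np.ndarray, int]:
    """Raw per-edge damage counts from variant-level edgetic annotations.

    w_{i,j} = number of annotations classified detrimental whose
    (gene, partner) pair matches edge {i, j} in either orientation.
    Beneficial and neutral annotations contribute 0.  Annotations whose gene
    pair is not an interactome edge are tallied and returned as the second
    element (warnings, never errors).

    Returns ``(W, n_unmatched)`` with W a symmetric nonnegative integer
    matrix (zero diagonal) aligned to ``nodes`` (default: sorted nodes).
    """
    if nodes is None:
        nodes = net.sorted_nodes()
    index = {g: i for i, g in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    n_unmatched = 0
    for ann in annotations:
        if not net.has_edge(ann.gene, ann.partner):
            n_unmatched += 1
            continue
        if ann.resolved_class() is not EdgeticEffect.DETRIMENTAL:
            continue
        i, j = index[ann.gene], index[ann.partner]
        w[i, j] += 1
        w[j, i] += 1
    if n_unmatched:
        logger.warning("%d annotation(s) did not match any interactome edge", n_unmatched)
    return w, n_unmatched


def transform_edge_weights(w, orientation: str = "increasing"):
    """Logistic map of raw damage counts into (0, 1).

    ``orientation="increasing"`` (default) uses 1 / (1 + exp(-w)), which is
    strictly increasing in the damage count: an undamaged edge carries 0.5
    and heavily damaged edges approach 1, so information flow favors damaged
    interactions.  ``orientation="decreasing"`` uses 1 / (1 + exp(w)) and is
    kept only for fidelity experiments with the opposite convention.

    Accepts scalars or arrays of nonnegative counts.
    """
    arr = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("damage counts must be finite")
    if np.any(arr < 0):
        raise ValueError("damage counts must be nonnegative")
    if orientation == "increasing":
        out = 1.0 / (1.0 + np.exp(-arr))
    elif orientation == "decreasing":
        out = 1.0 / (1.0 + np.exp(arr))
    else:
        raise ValueError(f"unknown sigmoid orientation: {orientation!r}")
    return out if out.ndim else float(out)


@dataclass
class WeightedNetwork:
    """A fully annotated network ready for propagation and extraction.

    Fields
    ------
    interactome:
        The underlying graph.
    nodes / node_index:
        Deterministic node ordering shared by all vectors/matrices.
    node_prior:
        Y, min-max-normalized -log10(P) priors in [0, 1] (0 for unscored).
    p_min, p_max:
        Raw-weight extremes retained for de-normalization.
    damage:
        W, symmetric integer matrix of disruptive-variant counts per edge.
    edge_weights:
        Logistic-transformed damage restricted to existing edges (non-edges
        stay 0); this is the matrix that gets degree-normalized for
        propagation.
    """

    interactome: Interactome
    nodes: list[str]
    node_index: dict[str, int]
    node_prior: np.ndarray
    p_min: float
    p_max: float
    damage: np.ndarray
    edge_weights: np.ndarray
    n_unmatched_annotations: int = 0
    sigmoid_orientation: str = "increasing"
    scores: GeneScoreTable | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        """Unweighted 0/1 adjacency aligned to ``nodes``."""
        import networkx as nx

        return nx.to_numpy_array(self.interactome.graph, nodelist=self.nodes, weight=None)


def build_weighted_network(
    net: Interactome,
    scores: GeneScoreTable,
    annotations: Iterable[EdgeticAnnotation],
    sigmoid_orientation: str = "increasing",
) -> WeightedNetwork:
    """Assemble node priors and edge weights into a :class:`WeightedNetwork`."""
    priors = compute_node_priors(scores, net)
    nodes = priors.nodes
    damage, n_unmatched = compute_edge_damage(annotations, net, nodes=nodes)
    adj = build_adjacency(net, nodes)
    sig = transform_edge_weights(damage, orientation=sigmoid_orientation)
    edge_weights = np.where(adj > 0, sig, 0.0)
    return WeightedNetwork(
        interactome=net,
        nodes=nodes,
        node_index={g: i for i, g in enumerate(nodes)},
        node_prior=priors.values,
        p_min=priors.p_min,
        p_max=priors.p_max,
        damage=damage,
        edge_weights=edge_weights,
        n_unmatched_annotations=n_unmatched,
        sigmoid_orientation=sigmoid_orientation,
        scores=scores,
    )


def build_adjacency(net: Interactome, nodes: Sequence[str]) -> np.ndarray:
    import networkx as nx

    return nx.to_numpy_array(net.graph, nodelist=list(nodes), weight=None)


def write_node_weights(wnet: WeightedNetwork, path: str | Path) -> None:
    """Dump gene, p_value, raw -log10 weight, and normalized prior per node."""
    pvals = wnet.scores.pvalues if wnet.scores is not None else {}
    with open(path, "w") as fh:
        fh.write("gene\tp_value\traw_weight\tprior\n")
        for i, gene in enumerate(wnet.nodes):
            p = pvals.get(gene)
            raw = "" if p is None else repr(-math.log10(p))
            fh.write(
                f"{gene}\t{'' if p is None else repr(p)}\t{raw}\t{float(wnet.node_prior[i])!r}\n"
            )


def write_edge_weights(wnet: WeightedNetwork, path: str | Path) -> None:
    """Dump gene_a, gene_b, damage count, transformed weight per edge."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tdamage_count\ttransformed_weight\n")
        for a, b in sorted(wnet.interactome.edges):
            i, j = wnet.node_index[a], wnet.node_index[b]
            fh.write(f"{a}\t{b}\t{int(wnet.damage[i, j])}\t{float(wnet.edge_weights[i, j])!r}\n")
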