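"""Evaluation procedures: seed recovery, module topology, reference overlap.

The central experiment is the seed-recovery ablation: a random fraction of
the seed genes is retained as input and the rest are held out; after
propagation, non-input genes are ranked by their propagated score and the
curve reports, as a function of the number k of top-ranked genes admitted,
the fraction of held-out seeds rediscovered.  Three weighting schemes are
compared:

* ``naive`` — no GWAS or damage information: every edge weighted 1 and the
  retained seeds given prior 1 (all other priors 0);
* ``gwas_only`` — every edge weighted 1, priors taken from the normalized
  GWAS gene scores;
* ``dimsum`` — the full weighting: logistic-transformed damage edge weights
  plus the GWAS priors.

The hold-out hides seeds from the *method input* (they are excluded from the
retained set and compete in the ranking); the GWAS annotation of the network
itself is the fixed upstream product and is not re-derived per replicate.

Genes with a propagated score of zero are never counted as recovered — with
no prior and no signal path they are indistinguishable from the bulk and
admitting them would credit arbitrary tie order.

Also provided: module overlap (count + Jaccard), internal connection
density, degree summaries of added genes, literature-reference match counts
and shared-GO-term counting on externally produced enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import WeightedNetwork
from .interactome import Interactome
from .propagation import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    normalize_adjacency,
    propagate,
)

__all__ = [
    "RecoveryCurve",
    "seed_recovery_experiment",
    "module_overlap",
    "connection_density",
    "added_gene_degrees",
    "count_literature_matches",
    "shared_enriched_terms",
    "read_enrichment_table",
]

RECOVERY_METHODS = ("dimsum", "gwas_only", "naive")


@dataclass
class RecoveryCurve:
    """Seed-recovery result for one method / replicate."""

    method: str
    holdout_fraction: float  # fraction of seeds retained as input
    rng_seed: int
    retained: list[str]
    held_out: list[str]
    fractions: np.ndarray  # fractions[k-1] = recovered fraction at top-k

    def at(self, k: int) -> float:
        """Recovered fraction of held-out seeds within the top-k ranked genes."""
        k = min(k, len(self.fractions))
        return float(self.fractions[k - 1]) if k >= 1 else 0.0


def seed_recovery_experiment(
    wnet: WeightedNetwork,
    seeds: Iterable[str],
    method: str,
    holdout_fraction: float,
    iterations: int = 100,
    rng_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RecoveryCurve:
    """Hold out seeds, propagate under ``method``'s weighting, rank, recover.

    ``holdout_fraction`` is the selection ratio: the fraction of seeds
    retained as input (e.g., 0.25 retains a quarter and tries to rediscover
    the remaining three quarters).  ``iterations`` is the maximum number of
    top-ranked non-input genes admitted (the curve's length in k).
    """
    if method not in RECOVERY_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {RECOVERY_METHODS}")
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    mapped = sorted(g for g in set(seeds) if g in wnet.node_index)
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped seeds to hold any out")
    rng = np.random.default_rng(rng_seed)
    n_retained = max(1, int(round(holdout_fraction * len(mapped))))
    n_retained = min(n_retained, len(mapped) - 1)
    retained = sorted(rng.choice(mapped, size=n_retained, replace=False).tolist())
    held_out = sorted(set(mapped) - set(retained))

    if method == "naive":
        m = wnet.adjacency()
        y = np.zeros(wnet.n)
        for g in retained:
            y[wnet.node_index[g]] = 1.0
    elif method == "gwas_only":
        m = wnet.adjacency()
        y = wnet.node_prior.copy()
    else:  # dimsum
        m = wnet.edge_weights
        y = wnet.node_prior.copy()

    result = propagate(normalize_adjacency(m), y, alpha=alpha, tol=tol, max_iter=max_iter)
    scores = result.scores

    input_idx = {wnet.node_index[g] for g in retained}
    ranked = sorted(
        (
            (i, wnet.nodes[i])
            for i in range(wnet.n)
            if i not in input_idx and scores[i] > 0.0
        ),
        key=lambda t: (-scores[t[0]], t[1]),
    )
    held_set = set(held_out)
    fractions = np.zeros(iterations)
    hits = 0
    for k in range(1, iterations + 1):
        if k <= len(ranked) and ranked[k - 1][1] in held_set:
            hits += 1
        fractions[k - 1] = hits / len(held_set)
    return RecoveryCurve(
        method=method,
        holdout_fraction=holdout_fraction,
        rng_seed=rng_seed,
        retained=retained,
        held_out=held_out,
        fractions=fractions,
    )


@dataclass(frozen=True)
class OverlapResult:
    count: int
    jaccard: float


def module_overlap(a: Iterable[str], b: Iterable[str]) -> OverlapResult:
    """Intersection size and Jaccard index of two gene lists."""
    sa, sb = set(a), set(b)
    union = sa | sb
    inter = sa & sb
    jaccard = len(inter) / len(union) if union else 1.0
    return OverlapResult(count=len(inter), jaccard=jaccard)


def connection_density(module: Iterable[str], net: Interactome) -> float:
    """Internal edges of the module divided by the number of possible pairs."""
    genes = sorted(set(module))
    m = len(genes)
    if m < 2:
        raise ValueError("connection density needs a module of >= 2 genes")
    present = [g for g in genes if net.has_node(g)]
    internal = sum(
        1
        for i, a in enumerate(present)
        for b in present[i + 1:]
        if net.has_edge(a, b)
    )
    return internal / (m * (m - 1) / 2)


@dataclass
class DegreeStats:
    genes: list[str]
    degrees: list[int]
    mean: float
    median: float
    max: float

    @property
    def empty(self) -> bool:
        return not self.degrees


def added_gene_degrees(module, net: Interactome) -> DegreeStats:
    """Interactome degrees of the module's non-seed (added) genes.

    Summary statistics are NaN when nothing was added.
    """
    added = [g for g in module.added if net.has_node(g)]
    degrees = [net.degree(g) for g in added]
    if degrees:
        arr = np.asarray(degrees, dtype=float)
        return DegreeStats(added, degrees, float(arr.mean()), float(np.median(arr)),
                           float(arr.max()))
    return DegreeStats(added, degrees, float("nan"), float("nan"), float("nan"))


def count_literature_matches(added: Iterable[str], reference: Iterable[str]) -> int:
    """Case-normalized exact intersection with a reference disease-gene list."""
    ref = {g.strip().upper() for g in reference if g and g.strip()}
    if not ref:
        raise ValueError("reference gene list is empty")
    return len({g.strip().upper() for g in added} & ref)


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    """Read a GO-enrichment result table (term_id, category, p_value)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"term_id", "category", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


@dataclass
class SharedTermsResult:
    shared_count: int
    candidate_enriched: int
    seed_enriched: int
    ratio: float  # shared / candidate_enriched
    per_category: dict[str, int] = field(default_factory=dict)
    shared_terms: set[str] = field(default_factory=set)


def shared_enriched_terms(
    seed_terms: pd.DataFrame,
    candidate_terms: pd.DataFrame,
    p_threshold: float = 0.01,
) -> SharedTermsResult:
    """Count enriched GO terms shared between seed and candidate gene pools.

    Both tables are filtered at p <= ``p_threshold``; the shared count is the
    intersection on term id, and the ratio normalizes it by the number of
    enriched terms in the candidate table.  A per-category (e.g., CC/MF/BP)
    breakdown of the shared terms is included.
    """
    for name, df in (("seed", seed_terms), ("candidate", candidate_terms)):
        missing = {"term_id", "category", "p_value"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table: missing columns {sorted(missing)}")
    seed_sig = seed_terms[seed_terms["p_value"] <= p_threshold]
    cand_sig = candidate_terms[candidate_terms["p_value"] <= p_threshold]
    shared = set(seed_sig["term_id"]) & set(cand_sig["term_id"])
    per_cat: dict[str, int] = {}
    cat_of = dict(zip(cand_sig["term_id"], cand_sig["category"]))
    for term in shared:
        cat = str(cat_of.get(term, "?"))
        per_cat[cat] = per_cat.get(cat, 0) + 1
    n_cand = len(set(cand_sig["term_id"]))
    ratio = len(shared) / n_cand if n_cand else 0.0
    return SharedTermsResult(
        shared_count=len(shared),
        candidate_enriched=n_cand,
        seed_enriched=len(set(seed_sig["term_id"])),
        ratio=ratio,
        per_category=per_cat,
        shared_terms=shared,
    )
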