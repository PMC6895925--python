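"""Comparison baselines: DIAMOnD-style and seed-connector (SCA-style) growth.

Both baselines share the seed set and interactome with the impact-score
method but deliberately ignore edge damage and GWAS magnitudes beyond seed
identity.

DIAMOnD ranks frontier genes by connectivity significance: the upper
hypergeometric tail probability of observing at least the candidate's number
of links into the current module, given its degree, the module size, and the
network size.  The gene with the smallest p-value joins, and significance is
recomputed against the grown module each step.

The seed-connector strategy instead grows the module by adding, each step,
the outside gene whose inclusion maximally enlarges the largest connected
component (LCC) of the induced subgraph, bridging initially disconnected
seed branches.  When no candidate enlarges the LCC, the candidate with most
links to the members is added (logged as a fallback).

Both are deterministic: ties are resolved by explicit rules (DIAMOnD: higher
degree, then lexicographic symbol; seed connector: *lower* total degree to
counter hub bias, then lexicographic), never by RNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
from scipy.stats import hypergeom

from .interactome import Interactome

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineModule",
    "BaselineStep",
    "connectivity_significance",
    "run_diamond",
    "run_sca",
]


@dataclass(frozen=True)
class BaselineStep:
    step: int
    gene: str
    statistic: float  # hypergeometric p (diamond) or resulting LCC size (sca)
    fallback: bool = False


@dataclass
class BaselineModule:
    """Module grown by a baseline method; seeds first, additions in order."""

    method: str  # "diamond" or "sca"
    seeds: list[str]
    members: list[str]
    step_log: list[BaselineStep] = field(default_factory=list)
    unmapped_seeds: list[str] = field(default_factory=list)

    @property
    def added(self) -> list[str]:
        return self.members[len(self.seeds):]


def connectivity_significance(candidate: str, module: Iterable[str], net: Interactome) -> float:
    """Hypergeometric upper-tail p-value of the candidate's links into the module.

    With N = |V| genes, K = module size, n = candidate degree and k_s = links
    from the candidate into the module, returns P(X >= k_s) for
    X ~ Hypergeometric(N, K, n).  A degree-0 candidate gets p = 1.
    """
    module = set(module)
    if candidate in module:
        raise ValueError(f"candidate {candidate!r} is already in the module")
    n_links = net.degree(candidate) if net.has_node(candidate) else 0
    if n_links == 0:
        return 1.0
    k_s = sum(1 for nbr in net.neighbors(candidate) if nbr in module)
    big_n = net.num_nodes
    big_k = len(module & net.nodes)
    # P(X >= k_s) = sf(k_s - 1)
    return float(hypergeom.sf(k_s - 1, big_n, big_k, n_links))


def _map_seeds(net: Interactome, seeds: Iterable[str]) -> tuple[list[str], list[str]]:
    seeds = sorted(set(seeds))
    mapped = [g for g in seeds if g.strip() and net.has_node(g)]
    unmapped = [g for g in seeds if g not in mapped]
    if not mapped:
        raise ValueError("no seed gene maps to the interactome")
    return mapped, unmapped


def run_diamond(net: Interactome, seeds: Iterable[str], max_additions: int = 100) -> BaselineModule:
    """Grow a module by iteratively adding the most connectivity-significant gene.

    Each step scores every non-member neighbor of the current module and adds
    the one with the lowest hypergeometric p-value; ties break toward higher
    interactome degree, then lexicographic gene symbol.  Plain variant: seed
    weights are not used.
    """
    mapped, unmapped = _map_seeds(net, seeds)
    members = list(mapped)
    member_set = set(members)
    mod = BaselineModule(method="diamond", seeds=list(mapped), members=members,
                         unmapped_seeds=unmapped)
    for step in range(1, max_additions + 1):
        candidates = sorted(
            {nbr for m in members for nbr in net.neighbors(m)} - member_set
        )
        if not candidates:
            break
        best = min(
            candidates,
            key=lambda g: (connectivity_significance(g, member_set, net), -net.degree(g), g),
        )
        p = connectivity_significance(best, member_set, net)
        members.append(best)
        member_set.add(best)
        mod.step_log.append(BaselineStep(step=step, gene=best, statistic=p))
    return mod


def _lcc_after_adding(graph: nx.Graph, comp_id: dict[str, int], comp_size: dict[int, int],
                      current_lcc: int, candidate: str) -> int:
    """LCC size of the induced member subgraph once ``candidate`` joins."""
    touched = {comp_id[nbr] for nbr in graph.neighbors(candidate) if nbr in comp_id}
    merged = 1 + sum(comp_size[c] for c in touched)
    untouched_max = max(
        (size for cid, size in comp_size.items() if cid not in touched), default=0
    )
    return max(merged, untouched_max, current_lcc if not touched else 0)


def run_sca(net: Interactome, seeds: Iterable[str], max_additions: int = 100) -> BaselineModule:
    """Grow a module by maximizing the largest connected component each step.

    Candidates are the non-member neighbors of current members (a gene with
    no member link cannot change the induced LCC).  Ties break toward lower
    total interactome degree (countering hub bias), then lexicographic
    symbol.  If no candidate enlarges the LCC, the candidate with most links
    to members is added instead and the step is flagged as a fallback.
    """
    mapped, unmapped = _map_seeds(net, seeds)
    graph = net.graph
    members = list(mapped)
    member_set = set(members)
    mod = BaselineModule(method="sca", seeds=list(mapped), members=members,
                         unmapped_seeds=unmapped)
    for step in range(1, max_additions + 1):
        candidates = sorted(
            {nbr for m in members for nbr in net.neighbors(m)} - member_set
        )
        if not candidates:
            break
        induced = graph.subgraph(member_set)
        comp_id: dict[str, int] = {}
        comp_size: dict[int, int] = {}
        for cid, comp in enumerate(nx.connected_components(induced)):
            comp_size[cid] = len(comp)
            for g in comp:
                comp_id[g] = cid
        current_lcc = max(comp_size.values())

        scored = [
            (_lcc_after_adding(graph, comp_id, comp_size, current_lcc, c), c)
            for c in candidates
        ]
        best_lcc = max(lcc for lcc, _ in scored)
        fallback = best_lcc <= current_lcc
        if fallback:
            # No connector improves the LCC: take the candidate with the most
            # member links (then fewer total degree, then lexicographic).
            best = min(
                candidates,
                key=lambda g: (
                    -sum(1 for nbr in net.neighbors(g) if nbr in member_set),
                    net.degree(g),
                    g,
                ),
            )
            new_lcc = current_lcc
            logger.debug("seed-connector fallback at step %d: added %s", step, best)
        else:
            tied = [c for lcc, c in scored if lcc == best_lcc]
            best = min(tied, key=lambda g: (net.degree(g), g))
            new_lcc = best_lcc
        members.append(best)
        member_set.add(best)
        mod.step_log.append(
            BaselineStep(step=step, gene=best, statistic=float(new_lcc), fallback=fallback)
        )
    return mod
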