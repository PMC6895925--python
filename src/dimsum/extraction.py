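"""Greedy impact-score module growth from the seed genes.

After propagation, each gene carries a relevance score; mapped back
(de-normalized) to the raw -log10(P) scale it plays the role of an updated
gene score p.  Starting from the seed set, the module grows one gene per
step: every immediate neighbor i of the current members is scored with the
impact score

    S(i) = p_i * sum_j w_{i,j},

where the sum runs over current module members j and w_{i,j} is the *raw*
count of disruptive variants on the interaction i-j (not the logistic-
transformed weight).  The highest-scoring neighbor joins the module; exact
ties are broken uniformly at random under a caller-supplied RNG seed.  The
loop stops after ``max_additions`` additions or when no neighbor remains.

When every candidate has S(i) = 0 (no damaged edge touches the frontier),
pure impact ranking is uninformative and the random rule alone would admit
noise genes; by default such steps instead rank candidates by their
de-normalized propagated score (flagged in the step log, and can be
disabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleState",
    "StepRecord",
    "denormalize_scores",
    "impact_score",
    "extract_module",
    "write_module_tsv",
]

DEFAULT_MAX_ADDITIONS = 100


def denormalize_scores(f: np.ndarray, p_min: float, p_max: float) -> np.ndarray:
    """Inverse of the min-max normalization: p_i = F_i * (p_max - p_min) + p_min."""
    if p_max < p_min:
        raise ValueError(f"p_max ({p_max}) < p_min ({p_min})")
    return np.asarray(f, dtype=float) * (p_max - p_min) + p_min


@dataclass(frozen=True)
class StepRecord:
    """One module-growth step: which gene was added and why."""

    step: int
    gene: str
    impact_score: float
    candidate_count: int
    tie_broken: bool
    fallback: bool  # True when the zero-impact score fallback ranking fired


@dataclass
class ModuleState:
    """Ordered module membership: mapped seeds first, then additions in order."""

    seeds: list[str]
    members: list[str]
    step_log: list[StepRecord] = field(default_factory=list)
    rng_seed: int = 0
    unmapped_seeds: list[str] = field(default_factory=list)

    @property
    def added(self) -> list[str]:
        return self.members[len(self.seeds):]

    @property
    def size(self) -> int:
        return len(self.members)


def impact_score(
    candidate: str,
    module_members: Iterable[str],
    p: float,
    damage: np.ndarray,
    node_index: dict[str, int],
) -> float:
    """S(i) = p * sum over module members j of raw damage counts w_{i,j}."""
    members = list(module_members)
    if candidate in members:
        raise ValueError(f"candidate {candidate!r} is already a module member")
    ci = node_index[candidate]
    total = sum(int(damage[ci, node_index[j]]) for j in members)
    return float(p) * total


def extract_module(
    wnet: WeightedNetwork,
    scores: np.ndarray,
    seeds: Iterable[str],
    max_additions: int = DEFAULT_MAX_ADDITIONS,
    rng_seed: int = 0,
    zero_score_fallback: bool = True,
) -> ModuleState:
    """Grow the module greedily by impact score from the mapped seed genes.

    Parameters
    ----------
    wnet:
        Fully weighted network (supplies the graph and raw damage counts).
    scores:
        De-normalized post-propagation gene scores aligned to ``wnet.nodes``.
    seeds:
        Seed genes; those absent from the interactome are reported in the
        result (not fatal), but at least one seed must map.
    max_additions:
        Number of genes to add (default 100); the loop stops early only when
        the candidate set is empty.
    rng_seed:
        Seed for the uniform tie-break among equally scored candidates.
    zero_score_fallback:
        Rank by de-normalized propagated score when every candidate's impact
        score is 0 (see module docstring); set False for the pure rule.
    """
    if max_additions < 0:
        raise ValueError("max_additions must be >= 0")
    scores = np.asarray(scores, dtype=float)
    seeds = sorted(set(seeds))
    mapped = [g for g in seeds if g in wnet.node_index]
    unmapped = [g for g in seeds if g not in wnet.node_index]
    if unmapped:
        logger.warning("%d seed(s) not in the interactome: %s", len(unmapped), unmapped[:10])
    if not mapped:
        raise ValueError("no seed gene maps to the interactome")

    graph = wnet.interactome.graph
    index = wnet.node_index
    members = list(mapped)
    member_set = set(members)
    state = ModuleState(seeds=list(mapped), members=members, rng_seed=rng_seed,
                        unmapped_seeds=unmapped)
    rng = np.random.default_rng(rng_seed)

    for step in range(1, max_additions + 1):
        # Frontier recomputed from scratch each step against the full current
        # module; optimizations must preserve step-for-step identity.
        candidates = sorted(
            {nbr for m in members for nbr in graph.neighbors(m)} - member_set
        )
        if not candidates:
            break
        member_idx = np.fromiter((index[m] for m in members), dtype=np.intp)
        cand_idx = np.fromiter((index[c] for c in candidates), dtype=np.intp)
        damage_sums = wnet.damage[np.ix_(cand_idx, member_idx)].sum(axis=1)
        s = scores[cand_idx] * damage_sums

        fallback = False
        key = s
        if zero_score_fallback and float(s.max()) == 0.0:
            fallback = True
            key = scores[cand_idx]
        best = key.max()
        tied = np.flatnonzero(key == best)
        tie_broken = len(tied) > 1
        pick = int(tied[0]) if not tie_broken else int(rng.choice(tied))
        gene = candidates[pick]

        members.append(gene)
        member_set.add(gene)
        state.step_log.append(
            StepRecord(
                step=step,
                gene=gene,
                impact_score=float(s[pick]),
                candidate_count=len(candidates),
                tie_broken=tie_broken,
                fallback=fallback,
            )
        )
    return state


def write_module_tsv(state, path: str | Path) -> None:
    """Write module membership: rank, gene, is_seed, impact_score, step.

    Works for greedy modules (:class:`ModuleState`) and baseline modules
    (anything with ``seeds``, ``members`` and an optional per-step score
    lookup via ``step_log``).
    """
    score_by_gene: dict[str, float] = {}
    for rec in getattr(state, "step_log", []):
        value = getattr(rec, "impact_score", None)
        if value is None:
            value = getattr(rec, "statistic", None)
        if value is not None:
            score_by_gene[rec.gene] = value
    n_seeds = len(state.seeds)
    with open(path, "w") as fh:
        fh.write("rank\tgene\tis_seed\timpact_score\tstep\n")
        for rank, gene in enumerate(state.members, start=1):
            is_seed = 1 if rank <= n_seeds else 0
            score = "" if is_seed else repr(score_by_gene.get(gene, float("nan")))
            step = 0 if is_seed else rank - n_seeds
            fh.write(f"{rank}\t{gene}\t{is_seed}\t{score}\t{step}\n")
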