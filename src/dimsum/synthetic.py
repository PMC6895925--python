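"""Planted-module synthetic benchmarks.

Generates the three inputs every pipeline stage consumes — an interactome,
a GWAS gene-score table, and variant-level edgetic annotations — with a
known ("planted") disease module, so the whole framework and its evaluation
experiments run without any external downloads.

The base interactome is a preferential-attachment (scale-free) graph, giving
the heavy-tailed, hub-dominated degree structure of the human interactome.
A randomly chosen planted gene set is densified to a target internal edge
probability, emulating a disease module.  A fraction of planted genes
("seed" genes) receive genome-wide-significant p-values (log-uniform in
``p_signal``); all other genes draw diffuse background p-values.  Disruptive
variant counts per edge are Poisson with a high mean on planted-internal
edges and a low mean elsewhere, and are emitted at the variant level (one
detrimental annotation row per count, assigned to a random endpoint gene)
so that edge-damage aggregation is exercised end to end.

Everything is reproducible from ``rng_seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import EdgeticAnnotation, GeneScoreTable, write_annotations
from .interactome import Interactome, write_edge_list

__all__ = ["SyntheticScenario", "ScenarioData", "generate_scenario", "read_truth"]


@dataclass
class SyntheticScenario:
    """Parameters of a planted-module benchmark.

    Defaults describe a mid-sized benchmark: a 1000-gene scale-free
    interactome with a 50-gene planted module densified to 15% internal edge
    probability, half of the planted genes carrying genome-wide-significant
    p-values, and disruptive-variant counts averaging 2.0 on planted-internal
    edges versus 0.05 elsewhere.
    """

    n_genes: int = 1000
    attachment: int = 3  # edges per new node during scale-free growth
    planted_size: int = 50
    planted_density: float = 0.15
    seed_fraction_of_planted: float = 0.5
    p_signal: tuple[float, float] = (1e-10, 1e-6)  # log-uniform bounds
    p_background: tuple[float, float] = (1e-4, 1.0)  # uniform bounds
    lambda_planted: float = 2.0
    lambda_background: float = 0.05
    ddg_detrimental: tuple[float, float] = (0.5, 3.0)  # uniform kcal/mol
    rng_seed: int = 0

    def validate(self) -> None:
        if self.planted_size > self.n_genes:
            raise ValueError("planted_size must be <= n_genes")
        if self.planted_size < 2:
            raise ValueError("planted_size must be >= 2")
        if not 0.0 < self.planted_density <= 1.0:
            raise ValueError("planted_density must be in (0, 1]")
        if not 0.0 <= self.seed_fraction_of_planted <= 1.0:
            raise ValueError("seed_fraction_of_planted must be in [0, 1]")
        if self.attachment < 1 or self.attachment >= self.n_genes:
            raise ValueError("attachment must be in [1, n_genes)")
        for lo, hi in (self.p_signal, self.p_background):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("p-value bounds must satisfy 0 < lo <= hi <= 1")
        if self.lambda_planted < 0 or self.lambda_background < 0:
            raise ValueError("Poisson means must be >= 0")


@dataclass
class ScenarioData:
    """Generated benchmark: inputs plus ground-truth planted labels."""

    interactome: Interactome
    scores: GeneScoreTable
    annotations: list[EdgeticAnnotation]
    planted: set[str]
    signal_genes: set[str]  # planted genes given significant p-values
    scenario: SyntheticScenario = field(repr=False, default_factory=SyntheticScenario)

    def truth_labels(self) -> dict[str, bool]:
        return {g: g in self.planted for g in sorted(self.interactome.nodes)}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write interactome.tsv, gene_scores.tsv, annotations.tsv, truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactome": outdir / "interactome.tsv",
            "gene_scores": outdir / "gene_scores.tsv",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_edge_list(self.interactome, paths["interactome"])
        self.scores.to_tsv(paths["gene_scores"])
        write_annotations(self.annotations, paths["annotations"])
        with open(paths["truth"], "w") as fh:
            fh.write("gene\tis_planted\n")
            for gene, is_planted in self.truth_labels().items():
                fh.write(f"{gene}\t{int(is_planted)}\n")
        return paths


def read_truth(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return {str(g): bool(v) for g, v in zip(df["gene"], df["is_planted"])}


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_scenario(cfg: SyntheticScenario) -> ScenarioData:
    """Generate a reproducible planted-module benchmark from ``cfg``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    # Scale-free base graph, relabeled to stable gene symbols.
    base = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attachment, seed=int(rng.integers(2**31 - 1))
    )
    net = Interactome()
    for i in base.nodes:
        net.add_node(_gene_name(i))
    for a, b in base.edges:
        net.add_edge(_gene_name(a), _gene_name(b), sources=("SYNTH",))

    genes = net.sorted_nodes()
    planted = sorted(rng.choice(genes, size=cfg.planted_size, replace=False).tolist())
    planted_set = set(planted)

    # Densify the planted set to the target internal edge probability.
    n_pairs = cfg.planted_size * (cfg.planted_size - 1) // 2
    target_edges = int(np.ceil(cfg.planted_density * n_pairs))
    internal = [
        (a, b)
        for idx, a in enumerate(planted)
        for b in planted[idx + 1:]
        if net.has_edge(a, b)
    ]
    missing = [
        (a, b)
        for idx, a in enumerate(planted)
        for b in planted[idx + 1:]
        if not net.has_edge(a, b)
    ]
    deficit = target_edges - len(internal)
    if deficit > len(missing):
        raise ValueError(
            f"planted density {cfg.planted_density} infeasible for size {cfg.planted_size}"
        )
    if deficit > 0:
        chosen = rng.choice(len(missing), size=deficit, replace=False)
        for k in sorted(chosen.tolist()):
            a, b = missing[k]
            net.add_edge(a, b, sources=("SYNTH",))

    # Gene scores: significant p-values on a fraction of planted genes,
    # diffuse background everywhere else.
    n_signal = int(round(cfg.seed_fraction_of_planted * cfg.planted_size))
    signal = set(rng.choice(planted, size=n_signal, replace=False).tolist())
    lo, hi = np.log10(cfg.p_signal[0]), np.log10(cfg.p_signal[1])
    blo, bhi = cfg.p_background
    pvalues: dict[str, float] = {}
    for g in genes:
        if g in signal:
            pvalues[g] = float(10.0 ** rng.uniform(lo, hi))
        else:
            pvalues[g] = float(rng.uniform(blo, bhi))
    scores = GeneScoreTable(pvalues)

    # Variant-level detrimental annotations: Poisson counts per edge,
    # concentrated on planted-internal edges.
    annotations: list[EdgeticAnnotation] = []
    variant_no = 0
    for a, b in sorted(net.edges):
        lam = (
            cfg.lambda_planted
            if a in planted_set and b in planted_set
            else cfg.lambda_background
        )
        count = int(rng.poisson(lam)) if lam > 0 else 0
        for _ in range(count):
            variant_no += 1
            mutated, partner = (a, b) if rng.random() < 0.5 else (b, a)
            ddg = float(rng.uniform(*cfg.ddg_detrimental))
            annotations.append(
                EdgeticAnnotation(
                    variant_id=f"v{variant_no:06d}",
                    gene=mutated,
                    partner=partner,
                    ddg=ddg,
                )
            )

    return ScenarioData(
        interactome=net,
        scores=scores,
        annotations=annotations,
        planted=planted_set,
        signal_genes=signal,
        scenario=cfg,
    )
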