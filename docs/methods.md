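# Methods

## Model and procedure

The package detects the subnetwork of a protein–protein interaction (PPI)
network most functionally impacted by a complex disease, by combining two
per-disease data products that are consumed, not computed, here: a gene-score
table (gene → aggregated GWAS p-value, the output shape of SNP-to-gene
aggregation tools) and a variant-level edgetic annotation table (variant,
mutated gene, interacting partner, ΔΔG in kcal/mol, the output shape of
structure-based interaction-effect predictors).

**Edgetic classification.** A variant's effect on one interaction is derived
from the binding free-energy change ΔΔG = ΔΔG_mt − ΔΔG_wt:
beneficial iff ΔΔG < −0.5 kcal/mol, neutral iff −0.5 ≤ ΔΔG < 0.5,
detrimental iff ΔΔG ≥ 0.5 (half-open intervals; both boundaries are
asserted in the tests). Only detrimental variants contribute damage;
beneficial variants are rare in real cohorts and are discarded along with
neutral ones. When a row carries both a ΔΔG and a stated class, ΔΔG wins
and disagreements are logged.

**Node weighting.** Gene i's raw weight is −log10(P_i). The base is a
convention choice (the min-max normalization below is invariant to it);
base 10 matches GWAS practice. P-values of exactly 0 are clamped to a
configurable floor (default 1e−300) with a logged count. Raw weights are
min-max normalized, Y_i = (raw_i − p_min)/(p_max − p_min), over the scored
genes; genes absent from the score table get Y_i = 0. If every raw weight
is equal the normalization is 0/0; scored genes then all receive 1.0 so
that scored genes still outrank unscored ones. p_min and p_max are retained
so propagated scores can be mapped back to the raw scale.

**Edge weighting.** w_ij is the integer count of detrimental variants on
either endpoint gene targeting interaction i–j. For propagation the counts
are passed through the logistic map w′_ij = 1/(1 + e^(−w_ij)), restricted
to existing edges (non-edges stay 0). The increasing orientation is the
default: an undamaged interaction conducts at 0.5 and damage raises
conductance toward 1, which matches the intent that flow should prefer
damaged interactions. The decreasing variant 1/(1 + e^(w)) is available via
`sigmoid_orientation="decreasing"` for fidelity experiments with the
opposite convention.

**Propagation.** F(t+1) = α W′ F(t) + (1 − α) Y with F(0) = Y and
W′ = D^(−1/2) W D^(−1/2), D(i,i) the row sum of the matrix being
normalized. Zero-degree rows map to zero rows (isolated nodes keep the
fixed point (1 − α) Y rather than being removed, so isolated seeds survive
to extraction). Since ‖W′‖₂ ≤ 1 the iteration contracts at rate α and the
fixed point is F* = (1 − α)(I − α W′)⁻¹ Y; the dense resolvent solve is the
independent oracle the tests compare against.

**Seed selection.** Bonferroni over the score table: seeds are genes with
P ≤ α_fam / m, with m the number of *scored* genes (the family actually
tested), α_fam = 0.05 by default.

**Extraction.** Propagated scores are de-normalized,
p_i = F_i (p_max − p_min) + p_min, and the module grows greedily from the
mapped seeds: each step ranks all immediate non-member neighbors of the
current module by S(i) = p_i · Σ_j w_ij, the sum running over current
members with *raw* integer damage counts (S counts mutations, so the
transformed weights are not used here), and adds the arg-max. Exact-tie
sets are sampled uniformly under a caller-supplied RNG seed; the candidate
frontier is recomputed from scratch each step against the full current
module. When every candidate has S = 0 (no damaged edge touches the
frontier) the pure rule degenerates to a uniform lottery; by default such
steps instead rank by the de-normalized propagated score, are flagged in
the step log, and can be disabled (`zero_score_fallback=False`).

## Baselines

Both baselines share the seed set and interactome and deliberately ignore
damage counts and GWAS magnitudes.

* **DIAMOnD-style.** Candidate rank is the hypergeometric upper tail
  P(X ≥ k_s) with population |V|, successes |module|, draws = candidate
  degree, k_s = links into the module; the minimum-p candidate joins and
  significance is recomputed against the grown module. Ties: higher degree,
  then lexicographic symbol. Seed weighting is not implemented.
* **Seed connector.** Each step adds the neighbor whose inclusion maximizes
  the LCC of the induced member subgraph. The tie rule (lower total degree
  first, then lexicographic) is this package's choice — the objective alone
  underdetermines the method — and intentionally counters the hub bias this
  family of methods is known for; when no candidate enlarges the LCC the
  candidate with most member links is added and flagged.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes: a
scale-free (preferential-attachment) base graph — hub-heavy like the human
interactome — with a planted module whose internal edge density is raised
to a target; genome-wide-significant p-values (log-uniform in
[1e−10, 1e−6]) on a fraction of planted genes and diffuse background
p-values (uniform in [1e−4, 1]) elsewhere; and per-edge detrimental-variant
counts Poisson(2.0) on planted-internal edges versus Poisson(0.05)
elsewhere, emitted as one annotation row per variant with ΔΔG drawn uniform
in [0.5, 3.0] kcal/mol. Defaults: 1000 genes, attachment 3, planted size
50, internal density 0.15, signal fraction 0.5 — sized so that the Bonferroni
threshold (0.05/1000 = 5e−5) separates signal from background exactly, the
planted module is an order of magnitude denser than the bulk, and a full
propagation–extraction run takes seconds.

What it does **not** emulate: linkage disequilibrium between gene scores,
realistic GWAS winner's-curse effect-size structure, annotation coverage
bias (real structural annotation covers only interactions with structures
or templates), false edgetic calls, and correlated noise between degree and
p-value. Passing tests on these benchmarks therefore demonstrate
correctness and the intended directional behavior of the integration, not
calibrated real-data performance.

## Seed-recovery experiment

A selection ratio (0.25 / 0.50 / 0.75) of the seed genes is retained as the
method's input; the rest are held out. Three weightings are compared —
naive (all edge weights 1, retained-seed priors 1, all other priors 0),
GWAS-only (edge weights 1, GWAS priors), and the full damage-aware
weighting. After propagation, non-input genes are ranked by propagated
score and the curve reports the fraction of held-out seeds within the top-k.
Two conventions matter and are deliberate:

* The GWAS prior vector is the fixed upstream annotation; holding out a
  seed removes it from the input seed list (and puts it into the ranking
  competition) but does not erase its p-value from the network annotation —
  that is how a partial seed list would be used against a fixed annotated
  network in practice. Consequently, prior-carrying configurations can
  saturate recovery at moderate k, and the ordering assertion treats pure
  ties as consistent with "at least as good" (any observed violations must
  be outweighed by a one-sided Wilcoxon rank test at 0.05).
* Genes with propagated score exactly 0 are never counted as recovered:
  with no prior and no signal path they are indistinguishable from the
  bulk, and crediting them would reward arbitrary tie order. This also
  makes the degenerate case exact: held-out seeds isolated from every
  retained seed are never recovered under indicator priors.

Quantitative recovery values from this experiment are scenario-dependent;
only the ordering (full ≥ GWAS-only ≥ naive at k = 100, 20 replicates) is
asserted.

## Numerical choices and defaults

| Parameter | Default | Notes |
|---|---|---|
| α (propagation trade-off) | 0.5 | fixed, not tuned |
| convergence tolerance | 1e−6 (L2 of update) | iterative vs. closed form agrees within 10× tol |
| max iterations | 1000 | non-convergence flags the result, never raises |
| module cap (max additions) | 100 | stops early only on candidate exhaustion |
| Bonferroni family α | 0.05 | family = scored genes |
| p-value floor | 1e−300 | clamps P = 0 before −log10 |
| ΔΔG thresholds | −0.5 / 0.5 kcal/mol | half-open intervals |

Dense linear algebra is used at these scales (≤ a few thousand nodes);
`normalize_adjacency`/`propagate` also accept scipy sparse matrices and the
tests pin sparse/dense agreement. Node order is lexicographic everywhere a
vector or matrix is indexed, making runs deterministic byte-for-byte under
a fixed RNG seed.

## Known limitations

* Gene identity is exact string match on symbols; no alias, isoform, or
  cross-database identifier resolution.
* Modules carry no significance estimate; the impact score ranks candidates
  but has no null model.
* The seed-connector baseline reproduces the published objective, not any
  specific release's tie-breaking, so gene-for-gene agreement with other
  implementations is not expected (the hypergeometric ranking of the
  DIAMOnD-style baseline is standard and should agree where ties are absent).
* The extraction loop recomputes the frontier each step; at interactome
  scale (10⁵ edges) a run takes minutes, not seconds, and no incremental
  shortcut is attempted because step-for-step identity is part of the
  contract.
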