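# Methods

## Model

`mdcap` scores miRNA–disease pairs for causal potential by diffusing the
known causal labels over two similarity networks — one over miRNAs, one over
diseases — and averaging the two diffusion results. The known causal
adjacency `A` (miRNAs × diseases) doubles as the label matrix `Y`.

### Similarity components

**Disease semantic similarity** uses the MeSH hierarchy. Each disease name
resolves to one or more tree numbers; the parent of a tree number is its
prefix truncated at the last dot, so the ancestor closure is computed purely
from strings. A term `k` hops above the disease contributes `δ^k`
(default `δ = 0.5`), taking the maximum when a term is reachable at several
depths (multiple tree numbers act as a DAG). The similarity of two diseases
is the summed contribution of shared ancestors normalised by the two total
semantic values. This is the standard Wang-style DAG similarity; an
information-content variant is deliberately out of scope.

**miRNA functional similarity** is the MISIM best-match average over the two
miRNAs' causal disease sets, restricted to diseases with a semantic profile.
A miRNA whose diseases all lack profiles has *undefined* (NaN) entries — a
missing value must not assert dissimilarity.

**GIP kernels** on both sides use the convention
`γ = γ′ / mean‖IP‖²` with `γ′ = 1`, i.e. the bandwidth adapts to the mean
squared profile norm of the network at hand.

**Hub promoted index** `|N(i)∩N(j)| / min(|N(i)|,|N(j)|)` is 1 on the
diagonal and 0 where the smaller neighbourhood is empty. It always dominates
the Jaccard index, favouring links to hubs.

### Integration and propagation

Per side, `S = w·primary + (1−w)·GIP` where the primary kernel is defined
and GIP alone elsewhere, followed by an additive HPI blend
`S ← (1−λ)S + λ·HPI`. Whether the original HPI "adjustment" was additive,
multiplicative or a replacement is not recoverable; the additive blend with
an exposed weight lets alternatives be tested (`λ = 0` disables it, `λ = 1`
replaces the kernel). Rows are normalised to sum 1; an all-zero row becomes a
unit self-loop so isolated entities keep their own labels rather than leaking
mass uniformly.

Label propagation iterates `F ← αWF + (1−α)Y` from `F⁰ = Y` until the
max-abs change falls below `tol` (default `1e−6`, cap 1000 iterations,
non-convergence raises with the last residual). For row-stochastic `W`,
binary `Y` and `α < 1` the fixed point `(1−α)(I−αW)⁻¹Y` is a convex
combination of stochastic averages of `Y`, hence every score stays in
`[0, 1]`; the iterative solution is verified against the closed form in the
tests. `α = 0` returns `Y` exactly. The two sides are propagated separately
(the disease-side operator acts on `Yᵀ`) and fused by the arithmetic mean,
which preserves the `[0, 1]` score reading.

### Defaults and parameter selection

| parameter | default | meaning |
|---|---|---|
| `delta` | 0.5 | semantic contribution decay per MeSH edge |
| `bandwidth_scale` | 1.0 | GIP `γ′` |
| `mix_weight` (`w`) | 0.5 | primary kernel vs GIP |
| `hpi_weight` (`λ`) | 0.5 | HPI blend |
| `alpha` | 0.5 | diffusion vs known labels |
| `tol`, `max_iter` | 1e−6, 1000 | convergence control |

The defaults are reasonable midpoints, not optimized values. The validation
protocol therefore includes the calibration step the method prescribes:
`evaluation.optimize_config` grid-searches the two integration weights
(`w ∈ {0, .25, .5, .75, 1}`, `λ ∈ {0, .25, .5}`) by k-fold cross-validation
on the training edges, and `protocol_benchmark` evaluates the selected
configuration on the untouched holdout. On the sparse synthetic benchmark
the CV reliably discovers that the GIP kernels carry little signal (their
interaction profiles are dominated by degree at that sparsity) and weights
the semantic/functional kernels up — the kind of dataset-dependent behaviour
the CV step exists to absorb. `alpha` and `delta` are kept fixed during the
search to bound its cost; both remain config keys.

## Evaluation protocol

`split_holdout` removes a uniform 20% of the causal edges;
`evaluate_split` rebuilds the network *and every similarity matrix* from the
training edges alone, so held-out edges cannot influence the model (asserted
bit-exactly in the tests). Held-out edges whose miRNA or disease is absent
from training are discarded and counted (`n_discarded`) — no prediction
exists for them. Positives are the retained held-out edges; negatives
default to *all* remaining non-associated pairs over the training entities
(the common convention for this model family), with a seeded
sampled-negatives mode (`negative_mode="sampled"`) as an alternative. AUC is
the normalised Mann–Whitney U statistic (ties half-credited), identical to
an exhaustive concordant-pair count; ROC points come from
`sklearn.metrics.roc_curve`. `repeat_evaluation` reruns either protocol with
seeds `base_seed + i` and reports per-run AUCs, mean and sd.

## Conservation analysis

`cdn` counts a miRNA's distinct causally linked diseases, `dsw` all distinct
associated diseases (`cdn ≤ dsw` is enforced). miRNAs are banded by cdn into
five groups (defaults 0, 1–5, 6–15, 16–30, >30; only the outer two bounds
are canonical, the inner cutoffs are config keys). SNPs are counted inside
precursor intervals with 1-based inclusive coordinates on both sides, strand
ignored, summed over a miRNA's precursor copies and collapsed by miRNA name.
Correlations of cdn/dsw against family size and SNP count report both
Pearson's r and Spearman's ρ — ρ is the safer statistic for count data — and
the optional min–max normalization of the x-axis cannot change either
coefficient (rank- and linearity-preserving).

## Synthetic data

The generator emulates the curated inputs at desk scale:

* **Association network** — a bipartite stochastic block model: entities are
  assigned round-robin to `n_blocks = 4` co-association blocks; edges appear
  with `p_within = 0.3` inside a block and `p_between = 0.02` across, over
  60 miRNAs × 40 diseases. Every edge becomes an association record whose
  evidence code is consistent with its causality flag
  (`causal_fraction = 1` by default, so the benchmark network is fully
  causal). Entities left without a causal edge are dropped with a warning
  rather than forced an edge, keeping edge probabilities honest.
* **Ontology** — one subtree per block; same-block diseases attach to leaves
  of the same subtree, so semantic similarity is informative about blocks
  and cross-block similarity is exactly 0.
* **Conservation fixture** — planted trends
  `family = max(1, round(1 + 0.3·cdn + ε))` and
  `snp = max(0, round(12 − 0.25·cdn + ε))`, `ε ~ N(0, 1)`, with cdn half
  zeros / half uniform on 1..30 to mimic the skew of curated data; families
  and SNP positions are materialised so file round trips preserve counts.

What passing these tests shows — and does not. The block model checks that
the pipeline recovers planted co-association structure end-to-end at honest
sparsity; it does not reproduce the degree distribution, the ontology depth,
or the scale of a real curated database, so benchmark AUCs (≈ 0.8 at
60 × 40) say nothing about the AUC reachable on the full curated data.
Problem sizes throughout (60 × 40 network, 5 seeds, 10 folds, 200-miRNA
conservation fixtures, 100-seed oracle sweeps) were chosen so the whole suite
and the acceptance script each run in well under a minute on one CPU while
keeping binomial noise far from the asserted margins.

## Numerical and degenerate-input choices

* Undefined similarity entries are NaN end-to-end and only resolved at
  integration time (GIP fallback); validation checks symmetry of both values
  and NaN patterns.
* Kernels are symmetrised (`(K + Kᵀ)/2`) and diagonals pinned to 1 to remove
  float drift before the `1e−12` symmetry checks.
* Ranking ties break lexicographically by entity name, making every ranking
  deterministic.
* Zero-degree pairs get HPI 0; an all-zero profile set makes the GIP
  bandwidth undefined and raises instead of dividing by zero.
* `roc_auc` refuses single-class inputs; constant scores give AUC 0.5 by the
  tie convention.
* All randomness flows through `numpy.random.default_rng(seed)`; repeated
  protocols derive per-run seeds as `base_seed + index`.

## Known limitations

* The prediction space is limited to miRNAs and diseases present in the
  causal network; entities outside it receive no scores.
* Disease names that do not resolve in the ontology fall back to pure
  topology (GIP/HPI) similarity.
* The exact published formula variants and optimized hyperparameter values
  for this model family are not public; the Wang/MISIM/GIP/HPI choices here
  are the canonical ones in this literature, and the CV step re-derives
  weights per dataset, but bit-compatibility with any specific prior
  implementation is not claimed.
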