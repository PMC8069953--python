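# Methods

## Statistical model

### Per-study effects and random-effects combination

For each study with n₁ cases and n₀ controls, a gene's effect is the
standardized mean difference d = (x̄₁ − x̄₀)/s_pooled with the pooled
(ddof = 1) standard deviation. Hedges' small-sample correction g = J·d,
J = 1 − 3/(4·df − 1), df = n₁ + n₀ − 2, removes the upward bias of d at
small group sizes; its large-sample variance is
v = (n₁+n₀)/(n₁n₀) + g²/(2(n₁+n₀)). Genes with zero pooled SD are excluded
(logged); duplicate gene rows (multiple probes) collapse to the row with
the largest |d| — deterministic and direction-preserving.

Across studies the DerSimonian–Laird estimator is used: fixed weights
wᵢ = 1/vᵢ give Cochran's Q; τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw));
random-effects weights wᵢ* = 1/(vᵢ + τ²) give the combined effect
μ = Σwᵢ*gᵢ/Σwᵢ*, the Wald statistic z = μ·√(Σwᵢ*), a two-sided normal
p-value, and Benjamini–Hochberg FDR across genes. Genes measured by only a
subset of studies (different platforms) are combined over the studies that
measure them, with `n_studies` recorded; no imputation. This classical
Hedges-g + DerSimonian–Laird chain was chosen over moderated-variance
effect estimators so the statistic is fully specified in-repo; a moderated
option is an extension point, not a default.

DEG calling applies strict inequalities — FDR < 0.05 and
|combined effect| > 2 — to the combined standardized scale.

**Calibration note.** Under a complete null the DL Wald z-test is
*conservative* at few studies: with three studies the raw-p rejection rate
at α = 0.05 is ≈ 0.03, not 0.05 (confirmed against an independent
random-effects implementation). Two mechanisms drive this: τ̂² > 0 under
the null inflates the standard error, and the g²-dependent variance
down-weights genes with large observed effects. The unit suite therefore
asserts the property that actually holds — validity (type-I ≤ α) — while
the acceptance suite keeps the stricter two-sided calibration band as
stated and documents its failure rather than weakening it. Power is
unaffected in the regime of interest: planted effects of 3 SD across three
10+10 studies are recovered with recall ≥ 0.9 at realized FDP ≤ 0.10.

### Disease module and LCC significance

The interactome is a simple undirected graph from STRING-style
protein-links files; edges need combined score ≥ 700 (inclusive, the
high-confidence threshold on the 0–1000 scale), reciprocal rows collapse,
self-loops are dropped and counted. Seed genes come from GDA tables with
score strictly > 0.01. The module is the induced subgraph of the mapped
seeds; significance of its largest connected component is judged against
LCC sizes of `n_permutations` (default 10,000) node sets of the same size
drawn uniformly from all interactome nodes — matching a size-matched
random-subnetwork null; a degree-preserving variant (log₂-degree-bin
matching) is available behind a flag but is not the default. The z-score
uses the null mean/SD (flagged undefined when the null SD is 0) and the
empirical p-value uses the add-one correction
(1 + #{null ≥ observed})/(n_permutations + 1), so it is never 0.

### DIAMOnD

At each iteration every non-member node with ≥ 1 link into the current
module is scored with the hypergeometric tail
p = Σᵢ₌ₖₛ^min(k,s₀) C(s₀,i)·C(N−s₀,k−i)/C(N,k), where N is the full
network node count (constant across iterations), s₀ the current module
size, k the node degree, ks its links into the module. The minimal-p node
joins and is recorded with its step; link counts are updated
incrementally, which the test suite proves exactly equivalent to
from-scratch recomputation. Seed weights are 1. Ties — including p-values
equal up to floating-point summation order (relative tolerance 1e-9) —
break deterministically: higher ks, then higher degree, then lexicographic
gene symbol. The default number of iterations equals the DEG count, so the
ranking prefix mirrors the signature size; it is configurable.

### Candidate genes and signature

Seed candidates: DEGs ∩ module, filtered to module hubs (degree ≥ 20
within the induced subgraph, inclusive per "at least"). Predicted
candidates: DEGs ∩ top-n DIAMOnD genes, filtered to hubs of the *full*
interactome; the hub threshold is reused (20) and configurable, since the
source analysis quantifies hubs only for the module. The signature union
carries provenance tags (a gene in both sets keeps the seed tag) and
up/down directions from the sign of the combined effect. Downstream, the
enrichment engine tests the *predicted candidate* set while the
anti-signature engine consumes the full signature.

### Drug engines

**Enrichment (direction-aware).** Interaction-type strings are normalized
(lower-case, comma-joined tokens) and matched exactly against a packaged
vocabulary of 43 inhibiting and 22 activating type strings; everything
else is `other` (logged once per distinct string). A drug–gene pair is
phenotype-reversing when an inhibiting interaction hits an up-regulated
signature gene or an activating one hits a down-regulated gene. Per drug,
p = P(X ≥ hits) for a hypergeometric draw of its background-restricted
target count from the N-gene background containing the candidate set —
targets are restricted to the background because the draw must come from
that urn. BH-FDR runs over all tested drugs (default: drugs with ≥ 1
reversing hit); the published FDR family size is unknown, so only raw
p-values are compared against published rows. Clinical-stage filtering is
delegated to an optional allow-list.

**Degree-z network ranking.** Drug–target tables (DrugBank/CTD sources
merged into one namespace with tags) are reduced to a bipartite network on
the signature genes; a drug's degree is its signature-target count. The
null redraws the gene list uniformly (default 1,000 replicates) from the
meta-analysis ∩ interactome background; z = (degree − null mean)/null SD,
one-sided normal p, BH-FDR, ranked FDR-then-z (raw-degree ranking is an
option since the published ordering rule is ambiguous), truncated to the
top 50. Zero null SD flags z as undefined; such drugs rank by degree.

**Anti-signature.** An explicit local approximation of signature-reversal
scoring against an L1000-style library: signed Jaccard similarity
J(q↑,s↑) + J(q↓,s↓) − J(q↑,s↓) − J(q↓,s↑) ∈ [−2, 2]; a direction-blind
overlap p-value (hypergeometric tail of the total up+down overlap against
the universe); BH q across the library; a robust z of the similarity
against the library's own similarity distribution (median/MAD scaled by
1.4826, mean/SD optional; MAD = 0 falls back to SD); combined = z·log₁₀(p),
an identity that reconstructs published combined scores from their printed
p and z within rounding. Hits sort ascending by similarity (most reversing
first). The true service-side similarity definition is not derivable from
printed values; only the combined-score identity is anchored.

## Synthetic data: what it emulates and what it does not

Expression: unit-variance Gaussian noise per gene with planted shifts of
±3 SD in cases, consistent across three 10+10 studies; per-study random
gene panels covering 80–100% of the universe emulate platform-coverage
differences. Microarray normalization artifacts, probe-level effects, and
gene–gene correlation are *not* modelled, so passing recovery tests
demonstrates the statistical chain, not robustness to array artifacts.
Interactome: Barabási–Albert preferential attachment (1,000 nodes, 3 edges
per new node) — heavy-tailed like a real PPI network but without its
community structure. Disease genes: breadth-first growth from a random
anchor (locality 1) down to uniform sampling (locality 0). Drug tables:
background drugs target uniform random genes with types sampled from the
published vocabulary plus neutral strings; planted reversers draw their
background targets outside the signature and add direction-opposing
in-signature pairs, so every in-signature pair they carry reverses.
The end-to-end fixture plants DEGs partly inside the module and partly
among its best-connected neighbours so the propagation stage has true
positives to find, and scales the hub threshold to 5 for its 1,000-node
network.

Null-calibration conditions for the drug engines use a 2,000-gene
universe, a 100-gene signature, 1,000 drugs with 200–800 targets each
(CTD-like promiscuity: single chemicals plausibly touch most of a
signature), and 1,000 random lists. Under these conditions the degree-z
p-values are indistinguishable from uniform (KS). The exact hypergeometric
enrichment p-values are *valid but discrete*: P(p ≤ x) = x holds only at
support atoms and P(p ≤ x) < x between them, so a literal KS-vs-uniform
test rejects at any realistic target-count regime. The unit suite asserts
sub-uniform validity on a grid; the acceptance suite keeps the literal KS
assertion as stated and documents its failure.

## Numerical choices and degenerate inputs

- Hypergeometric tails via the log-space-capable survival function;
  k = 0 returns exactly 1; results clipped to [0, 1].
- BH adjustment preserves input order, caps at 1, and is
  permutation-equivariant.
- Empty DEG sets halt the pipeline gracefully after the module stage with
  an explicit notice in the manifest; empty modules, empty candidate sets,
  and seeds covering the whole network degrade to empty outputs with
  warnings rather than errors.
- One global seed fans out to per-stage seeds by fixed offsets (LCC +1,
  drug network +2), so stages are independently reproducible and a rerun
  with the same config is byte-identical.

## Problem sizes

Default test and fixture sizes — 2,000-gene universe, three 10+10 studies,
1,000-node network, 50-gene module, 500-drug tables, 100-signature library,
1,000 LCC permutations in fixtures (10,000 remains the analysis default) —
were chosen as the smallest sizes at which every planted-recovery and
calibration property is stable across seeds.

## Known limitations

- The meta-analysis calibration band and the enrichment-null KS property
  discussed above are intrinsic to the chosen statistics, not tunable.
- Real-data identifier mapping (probe→gene, protein→symbol beyond the
  optional alias file, drug-name normalization across databases) is out of
  scope; all synthetic inputs share one symbol namespace.
- Gene lists and drug identities from the original analysis depend on
  external database snapshots (GEO, DisGeNET, STRING, DGIdb, DrugBank,
  CTD, LINCS) and are not reproduced; only snapshot-independent statistics
  are compared.
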