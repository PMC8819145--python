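# Methods

## Model and assumptions

`lnspf` scores every protein of an undirected simple PPI network for
essentiality under three biological assumptions: essential proteins cluster
together topologically (their neighborhoods overlap strongly), they are
evolutionarily conserved (high orthology counts), and they co-localize and
are co-expressed with their interaction partners. The method is
transductive — it ranks exactly the proteins of the input network; no model
is carried to other networks — and fully deterministic: there is no
randomness anywhere in the pipeline, only in the synthetic-data generator.

The pipeline has four stages:

1. **Feature extraction.** TP1 and TP2 sum, over a protein's one-hop
   neighbors, the fraction of shared one-hop and two-hop neighborhood
   membership. The two-hop set THNG(i) is the literal union of neighbors'
   neighborhoods, so it may contain the protein itself and its one-hop
   neighbors; this only rescales all of protein *i*'s TZ2 terms by a common
   denominator and keeps the formula exactly as defined. FP1 divides the
   summed squared compartment overlap by |NG(i)|+1 (the +1 is kept verbatim;
   it acts as smoothing). FP2 is the orthology score divided by the maximum
   over the universe. A zero-size denominator anywhere yields 0, so isolated
   or unannotated proteins never crash a run.
2. **Entropy-weight fusion.** The raw feature columns are normalized to sum
   to one across proteins (the entropy of a feature is only defined on a
   distribution; column normalization is the standard entropy-weight-method
   convention and is our choice — row normalization would entangle features).
   A feature whose distribution is near-uniform carries little ranking
   information and receives weight ≈ 0; a concentrated (low-entropy) feature
   receives a high weight. An all-zero column is assigned entropy 1 (weight
   0): a feature with no values carries no information, whereas the
   alternative convention (entropy 0) would hand a vacuous feature the
   largest weight. If every column is uninformative the weights fall back
   to uniform 1/M; both situations are logged.
3. **First propagation.** H couples every protein pair through the smaller
   of their fused scores, normalized by the total score mass. H is dense by
   design (the min-rule applies to *all* pairs); an edge-restricted variant
   is available behind `edge_restricted_h` but is not the default. Every
   row of H sums to at most 1, so the restart iteration
   Y ← αHY + (1−α)Y⁰ is a contraction for any α ∈ (0, 1) and converges to
   the unique fixed point (1−α)(I−αH)⁻¹Y⁰; the iterative loop is retained
   as the reference implementation and tested against the direct solve.
4. **Linear neighborhood similarity and second propagation.** For each
   protein with an expression profile and at least one expressed neighbor,
   the reconstruction weights minimize sᵀ(Gⁱ+μI)s over the probability
   simplex, where Gⁱ is the neighbor Gram matrix of profile differences.
   The QP is solved by a primal active-set method: exact equality-KKT
   solves on the current support, ratio-test steps that drop blocking
   coordinates, and dual-feasibility checks that add violating ones, with a
   1e-9 stationarity tolerance. Rows of S hold these weights plus a unit
   diagonal, so solvable rows sum to 2 and β·ρ(S) can reach or exceed 1 for
   β ≥ 0.5: the loop T ← βST + (1−β)T⁰ then diverges. Divergence is
   detected (residual growth or iteration cap) and reported as an error
   naming β and the estimated spectral radius — never returned silently —
   and an opt-in `row_normalize_s` flag divides solvable rows by their sum
   as a stabilization. Fidelity to the printed construction comes first,
   which is why normalization is not the default.

Proteins are finally sorted by T^Final in descending order; ties keep input
protein order (recorded in the output metadata).

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.6 | restart weight of the H loop; higher spreads more mass through the network |
| `beta` | 0.4 | restart weight of the S loop; must keep β·ρ(S) < 1 unless S is row-normalized |
| `delta` | 1e-6 | Euclidean convergence tolerance of both loops |
| `mu` | 1.0 | ridge term of the reconstruction QP; the derivation uses G+I and the final program G+μI, and μ = 1 reconciles the two |
| `max_iter` | 1000 | iteration cap per loop |

The defaults α = 0.6 and β = 0.4 are the settings reported to perform best
on the Gavin yeast benchmark; on other networks a grid sweep
(`lnspf sweep`) is the intended tuning route.

## Degenerate inputs and numerical choices

* Duplicate and self-interactions are filtered at parse time; proteins
  appearing only in annotation tables are ignored with a warning (the
  method is defined on the network's vertex set).
* Missing annotations default to an empty compartment set and orthology 0;
  a protein without an expression row (or without expressed neighbors)
  keeps a diagonal-only similarity row. An all-zero orthology table is
  rejected because the restart vector Y⁰ = FP2 would vanish.
* Convergence is measured in the Euclidean norm. The closed-form solve
  agrees with the iterative fixed point to within 10·δ and is used as an
  oracle in tests, never as the implementation.
* QP tie-breaking: for positive-semidefinite Gram matrices with μ = 0 the
  KKT system may be singular; a least-squares solve picks one minimizer
  (the objective value is unique even when the minimizer is not).

## Synthetic benchmark

The generator emulates the structure of the real data sources the method
targets: a Gavin-scale sparse interaction graph (preferential attachment,
default 300 proteins / 3 edges per node), 36-time-point periodic expression
profiles (two metabolic-like cycles of a shared sinusoid per essential
module plus unit-variance noise, baseline 5, clipped at 0), the 11-label
compartment vocabulary, and Poisson orthology counts. Four knobs plant the
essential signal: attachment bias (default 2.0), within-module expression
correlation ρ (0.6), core-compartment bias (0.8) and orthology enrichment
(3.0, over a background Poisson mean of 2). These defaults were chosen once
as a moderately-informative regime — each individual signal is noisy enough
that no single feature separates the classes — and `SyntheticSpec.null()`
switches all four off, giving label-independent data for calibration
checks.

What passing tests on these data do **not** show: real PPI networks have
study bias, false-positive edges, heavy-tailed annotation coverage and
missing expression rows at much higher rates; the generator's degree
distribution is cleaner than any experimental interactome; and real
essentiality labels are noisy. Results on the benchmark demonstrate the
implementation recovers planted signal of the assumed kinds, not field
performance.

## Known limitations

* The dense H matrix is O(N²) memory; networks beyond ~20k proteins would
  need the edge-restricted variant.
* β ≥ 0.5 typically diverges without `row_normalize_s`; this mirrors the
  printed construction of S and is reported loudly rather than silently
  repaired.
* No parameter auto-tuning is implemented beyond grid sweeps.
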