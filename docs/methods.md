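# Methods

## The problem and the model

`graphmer` learns *cis*-regulatory motifs by predicting gene expression from
promoter sequence, with no gene clustering step.  The inputs are a motif
matrix **X** (n genes × p k-mer counts, k ∈ {6, 7}, counted on the promoter
sense strand with overlaps) and an expression matrix **Y** (n genes × q
timepoints, log scale, replicate-averaged).  Both are column-standardized
(zero mean, unit population variance).  The model is partial least squares
(PLS) regression in its SIMPLS form: it constructs K weight vectors w_a ∈ R^p
whose latent factors t_a = X w_a have maximal covariance with directions
c_a in expression space, deflating the cross-product matrix S = XᵀY between
factors so the t_a stay mutually orthogonal.  **Y** is then regressed on the
latent factors by OLS (with a small-ridge fallback for rank-deficient T),
giving the coefficient matrix B = W·B_inner that maps standardized counts to
standardized expression.

Each factor pairs a k-mer weight vector w_a (which k-mers drive the factor)
with an expression weight vector c_a (the trajectory those k-mers drive).
We store c_a at unit norm; the spec of the decomposition fixes only its
direction, and unit norm makes trajectory correlations scale-free.  The sign
gauge is fixed per factor by flipping (w, t, c, u) jointly so the
largest-magnitude entry of c is positive; relative to any external reference
trajectory the gauge remains arbitrary, so analyses that compare a factor to
a known pattern orient w by the sign of corr(c, reference).

## Graph regularization

Two penalties make the weight vectors interpretable as motifs:

* **Sparsity.** Inside each factor's power iteration the intermediate
  solution is soft-thresholded, `w = sign(w̃)·max(|w̃| − δ, 0)` with
  δ = λ_lasso·max|w̃|.  The threshold is a *fraction of the current maximum*,
  which makes λ_lasso scale-free; δ is halved and reapplied if everything is
  zeroed.
* **Graph smoothness.**  k-mers are nodes of an unweighted graph with an
  edge wherever min(Hamming(a,b), Hamming(a, revcomp(b))) < θ (θ = 2 by
  default, i.e. at most one mismatch up to reverse complement; no edges
  between 6-mers and 7-mers by default).  With the Laplacian L = D − A the
  quadratic form wᵀLw = Σ_edges (w_i − w_j)² measures roughness over the
  graph, and the smoothing step solves (I + λ_graph·L) w̃ = S q (one sparse
  LU factorization per fit, reused across factors and iterations).

The per-factor inner loop alternates: q ← dominant right singular vector of
S; then repeat { z = Sq; solve the smoothing system; soft-threshold;
renormalize w; q ← Sᵀw/‖Sᵀw‖ } until max|Δw| < 1e-6 or 500 iterations
(non-convergence keeps the last iterate with a warning).  Successive iterates
are sign-aligned before the convergence test so the power iteration cannot
oscillate between the two equivalent fixed points.  With both penalties at
zero the loop converges to the dominant left singular vector of S in one
step, so the algorithm reduces *exactly* to SIMPLS — this limit is asserted
against an independent SVD oracle in the tests.

**Penalty defaults.**  λ_lasso = 0.1 and λ_graph = 5.0.  Under the
fraction-of-max thresholding rule, λ_lasso near 1 collapses the support to a
handful of k-mers; 0.1 prunes the diffuse tail (roughly half to three
quarters of weights exactly zero on the benchmark) while leaving well over
the 50 k-mers that the graph-mer analysis inspects.  λ_graph = 5 weights the
smoothing solve strongly enough that graph neighborhoods (a consensus and
its one-mismatch variants) move as units, which is the stated purpose of the
penalty; both were calibrated on the synthetic benchmark and are exposed as
configuration options.

## Error metric and model selection

Prediction error is the normalized mean squared error,
NMSE = Σ(Y − Ŷ)² / Σ(Y − mean(Y))², pooled over all matrix cells, so the
zero-factor (mean) predictor scores exactly 1.  In cross-validation the K = 0
entry is that test-mean predictor and is exactly 1 by construction.  Folds
are a seeded permutation of genes (10 folds by default); standardization
statistics come from the training split only; the model is fitted once with
K_max factors per fold and evaluated truncated to every K; the chosen K is
the argmin of the mean curve, smallest K on ties.  Gene-subset NMSE profiles
normalize by the subset's own variance around its grand mean (so singleton
sets are well-defined; on standardized data the full-set profile coincides
with the global one) and report per-factor loss reductions
Δ_K = NMSE(K−1) − NMSE(K).

As a negative control, `randomize_pairing` permutes the rows of **Y** with a
seeded permutation, preserving both marginals while destroying the
sequence-to-expression correspondence; held-out NMSE then rises above 1 at
the first factor.

## Feature filtering

k-mers that barely occur carry no signal and inflate the feature space.  The
background model mononucleotide-shuffles each exon sequence 100 times
(preserving per-sequence base composition exactly; windows never cross
sequence boundaries) and estimates a per-position background frequency
p = count/N with N the total shuffled length.  Each observed k-mer is scored
with a binomial z,  z = (n − L·p) / sqrt(L·p·(1 − p)), where n is its total
promoter count and L the total number of promoter windows of its length —
i.e. the observed count is compared against its expectation *over the
promoter positions* at the background rate.  k-mers never seen in the
background score +∞ and rank first.  The top m = 2000 k-mers by z (stable
lexicographic tie-break) are retained.

## Motif extraction

For each factor, the top 50 k-mers by (positive) weight form a "graph-mer":
the weight vector restricted to its strongest support, with the induced
similarity subgraph.  Dense modules are found with the MCODE
vertex-weighting algorithm (node score = highest k-core number of the closed
neighborhood × that core's density; greedy expansion from the best seed
including neighbors within `vwp = 0.2` of the seed score; haircut removes
members attached by a single edge; singletons are discarded).

Each module is collapsed into a PSSM by hierarchical agglomeration.  A
k-mer seeds the PSSM θ_j(b) = (1−ε)[b = s_j] + ε·q(b) with ε = 0.1 and q the
promoter mononucleotide composition; its target count is the number of
promoters containing it.  The distance between two PSSMs is the minimum over
all overlapping offsets of the summed per-position Jensen–Shannon divergence
(base-2 logs), with mixture weights π_i proportional to target counts and
non-overlapping flanks padded with the background distribution.  The closest
pair is merged (position-wise mixture at the best offset; target counts add)
until one PSSM remains — m seeds always take exactly m − 1 merges.  Ties in
the pair search break on the smallest index, making the procedure
deterministic.  PSSMs are written in MEME minimal format (nsites = target
count).

## Gene–factor assignment and validation statistics

The gene–factor score is s_{g,i} = T[g,i]·U[g,i], the product of the
input-side and output-side latent scores; it is invariant under the joint
sign flip of (w_i, c_i).  A gene is assigned to its argmax factor only when
that score reaches the top 20% of the pooled best-score distribution; by
default five factors are used and genes landing on the fifth are excluded
from downstream motif gene lists (it acts as a sink for residual structure).
Within a factor's gene group, genes are ranked by total counts of the
motif's member k-mers (score-descending tie-break).

Positional bias: every occurrence (either strand) is located by the distance
of its TSS-proximal end, in bp upstream (1 = immediately upstream of the
TSS; promoters are stored 5'→3' with the TSS at the right end).  Two gene
groups are compared by the fraction of occurrences within 200 bp and a
one-sided two-sample Kolmogorov–Smirnov test for the in-group distances
being stochastically smaller.

Motif conservation score (MCS): for a k-mer with n occurrences in species-A
promoters of ortholog-bearing genes, of which n_c are "conserved" (the k-mer
or its reverse complement is present anywhere in the ortholog's promoter),
MCS = (n_c − n·p̂)/sqrt(n·p̂(1−p̂)), with p̂ the mean conservation rate of 500
uniformly drawn random k-mers of the same length (seeded draw).  Presence
anywhere in the ortholog window is deliberately alignment-free; the MCS
inherits the composition confound of the underlying statistic (AT-rich
k-mers are conserved by chance more often), which is why contrasts are
always against the same-background random-k-mer distribution.  Top-versus-
remainder contrasts of per-gene-set MCS differences use a one-sided KS test.

## The synthetic benchmark

The generator emulates the model's own generative assumption: promoters are
i.i.d. mononucleotide background (36% GC, worm-like), 500 bp; each of two
planted motifs — the CG-rich `GCGCGC` and the E-box `CACGTG`, with
orthogonal unit-norm trajectories (a late rise and a mid-course peak over 12
timepoints) — marks a disjoint 20% of the 1000 genes as targets; each target
promoter receives 4 non-overlapping copies, each copy independently mutated
at rate 1/6 per base (one expected substitution per site, a typical
degeneracy for a 6-bp binding site) and inserted on a random strand;
expression is β·(copy count)·c* summed over motifs plus N(0, 0.5²) noise.
The condition choices are biologically anchored: functional promoters
commonly carry several binding-site copies, germline-specific gene sets
comprise roughly 15–25% of filtered genes in the kind of developmental data
this method targets, and a site with one expected mismatch exercises the
graph smoothing meaningfully.  Ortholog fixtures draw fresh background
promoters and copy each planted occurrence over with a fixed conservation
probability.

What the generator does *not* emulate: nucleosome structure, low-complexity
and repeat sequence, correlated replicate noise, cooperative/synergistic
site interactions, and motif positional preferences.  Passing the benchmark
therefore demonstrates that the algorithm recovers planted linear
sequence-to-expression structure under realistic noise — not that it defeats
the confounds of real promoters (the low-complexity problem in particular is
only partially probed).

Two structural facts about the benchmark are worth knowing when reading
results.  First, planting a k-mer also plants its *shifted* junction k-mers
(each 1-shift string inherits ~25% of all copies versus ~2% for each point
mutant), so top-50 graph-mers legitimately contain many shifted variants —
the offset-aware agglomeration exists precisely to merge them.  Second,
recovery quantities (neighborhood capture, trajectory correlation) are
reported as means over replicate × factor cells: individual cells fluctuate
with the seed because point-mutant signals sit near the selection boundary,
while the means are stable.  One-mutant capture counts reverse-complement
equivalence classes, since the graph treats a k-mer and its reverse
complement as the same variant.

## Problem sizes and numerical choices

The benchmark runs at 1000 genes × 12 timepoints with the top 2000 of
~20,000 6/7-mers, five replicate seeds for recovery, 10-fold CV, and 500
random k-mers for conservation calibration; a full replicate (generation,
features, CV, fit, evaluation) takes a few seconds on one CPU.  Tolerances:
inner-loop convergence 1e-6 (max-norm); PSSM rows sum to 1 within 1e-9;
Laplacian identity asserted to 1e-9; SIMPLS oracle equivalence to 1e-6.
Degenerate inputs: constant expression columns are zeroed and flagged during
standardization; an exhausted cross-covariance matrix stops factor
extraction early with a warning; a k-mer absent from promoters cannot enter
the count matrix by construction.

## Known limitations

* The gene–factor score form (product of latent scores) and the exact
  inner-loop schedule of the regularized fit are reconstructions of
  under-specified parts of the method; both are documented above and
  the score form is configurable (`product` | `min`).
* Orthogonality of latent factors is exact for plain SIMPLS but only
  approximate under the penalties (deflation still projects out loadings,
  but thresholded weights leave the deflated column space); the final
  regression therefore never assumes orthogonality.
* MCS is promoter-window based and alignment-free; it does not use genome
  alignments or branch lengths.
* Cross-length (6-mer vs 7-mer) graph edges are available but off by
  default; Hamming distance between unequal lengths is otherwise undefined.
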