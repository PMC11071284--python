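# Methods

## Evolutionary models

Per-gene expression on a rooted subline phylogeny is modelled as a
Gaussian process along branches. Under Brownian motion (neutral
evolution) a tip at depth `T_i` has variance `σ²T_i` and two tips
covary by `σ²·t_a`, the depth of their most recent common ancestor.
Under an Ornstein–Uhlenbeck process with selection strength `α` and
piecewise-constant optimum `θ(t)` (set by the branch regime), the tip
mean is the Hansen weighted average

    E[X_i] = x₀ e^{−αT_i} + Σ_segments θ_r (e^{−α(T_i−e)} − e^{−α(T_i−s)})

over the regime segments `[s, e]` of the root-to-tip path, and tip
covariance (root state held fixed)

    Cov(X_i, X_j) = e^{−α(T_i+T_j−2t_a)} (1 − e^{−2αt_a}) σ²/(2α),

which reduces to the BM covariance as `α → 0` (that branch is taken
exactly at `α = 0`). The ancestral state is tied to the background
optimum (`x₀ = θ₀`) for OU models, as in Hansen-style implementations;
for BM `x₀` is a free mean. Replicate cells add independent noise of
variance `γσ²`, giving the cell-level covariance `σ²(Z V₀ Zᵀ + γI)`
with `Z` the cell→subline indicator.

Free parameter counts: BM 3 (`x₀, σ², γ`), one-optimum OU 4
(`θ, α, σ², γ`), two-optima OU 5 (`θ₀, θ₁, α, σ², γ`).

## Estimation and testing

Because the mean is linear in θ and the covariance scales by σ², both
are profiled in closed form: θ̂ by GLS through a Cholesky-whitened
least-squares solve (SVD-based, so near-collinear designs at small α
degrade gracefully), σ̂² = RSS/n (ML, not REML, so likelihood-ratio
tests are on the ML scale). The remaining search over `(log α, log γ)`
uses bounded L-BFGS-B, `α ∈ [10⁻⁴, 10³]`, `γ ∈ [10⁻⁶, 10²]`, started
from (0.1, 0.01) plus two fixed multiplicative jitters (×20, ×0.05) to
escape local optima; BM searches γ only. Adaptive (two-optima vs BM,
df 2) and constrained (one-optimum vs BM, df 1) LRT statistics are
clamped at 0 and referred to χ²; df is the free-parameter difference.
BH-FDR correction is applied across genes, separately per regime and
separately for the two tests; calls use corrected p < 0.05, with
up/down by the sign of θ̂₁ − θ̂₀.

Degenerate inputs fail per gene, not per run: constant genes, exactly
singular covariances (γ = 0 with replicated sublines), and
non-convergent optimizations are skipped and counted; a run aborts only
if the failed fraction exceeds a configurable threshold (default 20%).

## Tree handling

Branch lengths are taken as given (expressed-mutation counts) and the
tree is rescaled to unit height. The models are invariant under joint
rescaling (`t → ct`, `α → α/c`, `σ² → σ²/c`), so this is a unit
convention, not an assumption; it makes α and σ² comparable across
datasets. Regime painting marks a branch "chosen" exactly when every
tip below it is chosen, i.e. each maximal chosen-only clade including
its stem; the root is always background. Zero-length branches are
permitted (soft polytomies); zero-length terminal branches are logged.

## Expression scale

The analysis transform is `log2(TPM + 1)` by default ("identity" is
available). A Gaussian process on raw TPM is untenable given its
dynamic range; the simulator's TPM-like output applies the exact
inverse (`2^x − 1`, clipped at 0) so that simulation → transform →
scan is self-consistent. Gene filtering defaults to "expressed (> 0)
in ≥ 50% of cells and nonzero variance".

## Synthetic data

The generator draws exact branch-wise transitions (no
time-discretization error): BM children are `N(parent, σ²t)`; OU
children are `N(parent·e^{−αt} + θ(1−e^{−αt}), σ²(1−e^{−2αt})/2α)`.
Defaults mirror the study conditions: a 23-tip fixture tree with three
monophyletic phenotype clades (HA-R: C11/C15/C18/C16, HA-S: C1/C4/C22,
LA-S: C3/C10/C14) and arbitrary mutation-count-like branch lengths;
1–8 cells per subline; σ² = 1 on the unit-height tree; noise grid
γ ∈ {0.01, 0.1, 0.5}; adaptive grid α ∈ {2, 10, 50} × optima gap
{0.5, 1, 2} (log₂ units around a baseline of 5 ≈ 31 TPM). Per-gene
RNG streams derive from `(master seed, condition index, gene index)`,
so outputs are byte-reproducible and subset-stable. The generator does
not emulate count-level single-cell artifacts (dropout, library size,
negative-binomial noise); passing tests therefore demonstrate
correctness of the evolutionary machinery under its own assumptions,
not robustness to every property of real single-cell data.

## Simulation study

The validation driver simulates neutral genes across the noise grid
(default 170 genes × 6 conditions = 1020), scans them (one BH family
per replicate level), and reports the percent called adaptive; it
benchmarks a naive Welch t-test between chosen-clade cells and
background cells on the same data with the same BH threshold. The
t-test treats correlated cells as independent samples, so neutral
drift along shared branches masquerades as group differences — its
false-positive rate lands far above both the nominal level and the
scan's. Power uses 200 genes at the grid's most
favorable condition (gap 2, α = 50, γ = 0.01, 8 cells/subline). These
problem sizes keep the full study within minutes on one CPU while the
binomial standard error on reported percentages stays around a
percentage point.

## Known limitations

* **α is weakly identified when selection is strong.** Once
  `α·T ≳ 10`, tips sit near their stationary distribution and the
  likelihood is nearly flat in α with only the compounds `σ²/(2α)`
  (stationary variance) and `γσ²` (cell noise) identified. The MLE of
  α then spreads widely along this ridge and σ̂² inherits the spread;
  optima and all likelihood-ratio calls are unaffected. Parameter
  recovery checks at α = 20 show the identified compounds recovered to
  a few percent while α̂ and σ̂² individually are biased upward.
* Constrained (one-optimum OU) evolution is hard to separate from
  neutrality at realistic noise; the constrained test is computed and
  reported, but adaptive calls are the headline output.
* k selection by silhouette supports both "highest" (conventional,
  default) and "lowest" criteria, since published protocol wordings
  differ; the choice is explicit in the result object.
* The signed log₂ value feeding the clustering uses the corrected p
  (q) by default, with a switch for raw p; note up-regulated genes get
  *negative* values (log₂ of p < 1), with a display-only sign flip
  available.
* The DE comparator in the simulation study applies BH at 0.05,
  mirroring the scan's threshold policy, so the head-to-head is fair.
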