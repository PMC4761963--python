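# Methods

## Model and procedure

`tfbsreg` treats a promoter's regulatory input as additive in binding-site
dosage. For gene *g* with hit counts *x₉ₘ* of binding-site model (PWM) *m*,
the modelled condition's expression on the log₂ scale is

    E[y_g] = β₀ + Σ_m RC_m · x_gm ,

where *y_g* is the per-gene mean of log₂(FPKM-like + 1) across the
condition's replicates and RC_m is the regression coefficient of TFBS *m*.
The pipeline estimates which RC_m are nonzero, with what sign, and whether
the sign agrees between two treatment conditions.

### Up-regulation and DUGs

Genes are called up-regulated vs control when FC > 2 and q < 0.05, with
FC = (mean_treated + ε)/(mean_control + ε), ε = 1.0 (guards zero division
on FPKM-scale data; configurable). The per-gene test is Welch's t on
log₂(x+1) replicate values — the pipeline's thresholding logic is the
contract; the test engine is deliberately simple and pluggable, not a
reimplementation of any specific DE package. FDR is Benjamini–Hochberg.
Genes with zero variance in both groups take p = 1 by convention.
Differentially up-regulated genes (DUGs) are up-regulated genes whose
condition-mean ratio between the two treatments exceeds 2 (same ε); the
gene must be up-regulated vs control in the favored condition. "Expressed"
uses mean abundance > 1.0 in at least one condition (conventional floor,
configurable). Set overlaps use the upper-tail hypergeometric probability
with Bonferroni correction; generic category enrichment uses the same
machinery with caller-supplied category maps.

### Motif scoring

PWMs are per-position base-frequency matrices (TRANSFAC-dialect and
JASPAR readers; counts get a 0.01 pseudocount per cell before
normalization). The information vector I(i) = Σ_b f(i,b)·ln(4·f(i,b)) is
0 for uniform positions and ln 4 for invariant ones; the core is the
5-position window maximizing summed information (ties → leftmost). A
window scores MSS = (Current − Min)/(Max − Min) with
Current = Σᵢ I(i)·f(i,bᵢ); CSS is the same restricted to the core. 'N'
bases contribute the row minimum so ambiguity can never create a hit.
Both strands are scanned (minus strand = reverse-complement matrix on
the forward sequence); hits are reported in plus-strand 0-based
half-open coordinates. Scores are clipped to [0,1] and values within
1e-9 of the ends are snapped, so consensus windows score exactly 1 and
cutoff-1.0 scans recover planted consensus sites. Default cutoffs are
MSS ≥ 0.85 and CSS ≥ 0.90 — fixed conservative values standing in for
per-matrix cutoff profiles that cannot be shipped, overridable per scan.
Features are hit *counts* (dose information for the linear model); all
overlapping hits are kept, since counts feed a regression rather than an
annotation track.

### Model search and bootstrap RC distributions

`search_models` minimizes an information criterion over feature subsets
of size ≤ `max_model_size` (default 10): exhaustive enumeration when the
subset count fits a budget (default 10⁶; ties favor smaller subsets,
then feature order), greedy forward selection otherwise. The default
single-search criterion is BIC (n·log(RSS/n) + k·log n) — it penalizes
size, making "best combination" well defined; adjusted R² is available.

`bootstrap_rcs` resamples genes with replacement B times (default 1000),
reruns the search per replicate, and records each selected TFBS's
coefficient; a TFBS absent from a replicate's model contributes RC 0, so
every distribution has exactly B entries. Degenerate resamples
(constant response) are redrawn, at most 10·B attempts. An alternative
scheme — B random feature-subset fits on the full gene set — is
implemented behind the same interface (`scheme="subset"`); neither
scheme is claimed to be uniquely canonical. Significance of a
distribution is a two-sided one-sample t-test of the B RCs against 0
with Bonferroni correction over the TFBSs tested, α = 0.01. Degenerate
cases: zero-variance RCs with zero mean are never significant;
zero-variance with nonzero mean always are.

**Selection-penalty calibration.** Inside the bootstrap, BIC is the
wrong penalty. The downstream t-statistic grows like √(B·f/(1−f)) in a
TFBS's selection frequency *f*, so any null feature admitted with a
consistent sign in even ~7% of replicates (at B = 200) becomes
Bonferroni-significant; BIC's entry threshold (partial |t| ≈ √log n ≈
2.4) admits the best chance-correlated null far more often than that,
and measured null false-positive rates approach 50%. The bootstrap
therefore defaults to a generalized information criterion
n·log(RSS/n) + λ·k with λ = z², z the normal quantile at
α/(2·p·B) — a Bonferroni bound on false inclusion across all ~p·B
candidate entry tests of the resampling scheme (λ ≈ 20.8 at p = 10,
B = 200). Under the synthetic study conditions this recovers planted
RC signs in 100% of repetitions while flagging nulls in under 1% of
TFBS-repetition pairs; `criterion="bic"` restores the classical
behavior.

Between-condition classification: a TFBS significant in both conditions
with equal mean-RC signs is *identical*, with unequal signs *opposite*;
significant in exactly one, *unique* to it. `refit_excluding` reruns the
identical pipeline with a gene subset removed and reports per-TFBS mean
RC shifts — the analysis used to show that a coefficient's sign can be
driven entirely by one gene subpopulation (e.g. a keratin-like cluster).

### Network assembly

Candidate TFs are those bound to a significant TFBS whose own coding
gene is up-regulated (unmapped TF names are dropped with a warning).
Edge (t, g) exists iff some PWM of t has feature count > 0 in g's
promoter. Edges are unweighted binding-presence links stored as directed
(tf, gene) pairs; a TF whose gene is itself a DUG is a single node with
both roles. Unlinked DUGs are surfaced via `unlinked_genes`, never
silently dropped. Merging is node/edge set union with condition labels
normalized to sorted ';'-joined form (making merge idempotent,
commutative and associative). Exports: SIF, GraphML (node roles,
condition labels, out-degree — suitable for sizing nodes by target
count), and 2-column edge lists.

## Synthetic data

The generator is the pipeline's ground truth. Promoter background is
i.i.d. uniform over {A,C,G,T} — the simplest null consistent with the
uniform-background information formula. Planted occurrences write the
PWM's consensus string (reverse-complemented on the minus strand), not
probabilistic draws, so cutoff-based recovery is exactly testable:
a planted window always scores MSS = CSS = 1. Simulated PWMs draw each
position from a Dirichlet with one dominant base (concentration 10 vs
0.5), giving sharp motifs whose consensus probability is well above
background. Expression is 2^(linear predictor + N(0, noise_sd)) − 1
clipped at 0, so the downstream log₂(x+1) transform inverts the link
exactly away from the floor; replicates differ only by noise. Each
generator operation draws from its own independently seeded RNG stream,
so adding an operation never perturbs another's output.

Default study conditions: 300 genes, 10 PWMs of width 8–12, promoter
length 1200 (matching the conventional −1000..+200 promoter window),
plant rate Poisson(1.0) per gene × motif, two causal motifs with
RCs ±2.0, intercept 3.0, noise_sd 0.5, 4 replicates per condition,
B = 200 bootstrap replicates in the bundled experiments (B = 1000 is
the library default for real analyses; 200 keeps repeated simulation
studies fast while leaving the t-test amply powered).

What the generator does *not* emulate: read-level sampling noise
(counts come from a clean Gaussian log-scale model), isoforms, GC or
mappability bias, correlated replicate structure, motif co-occurrence
grammar, and dinucleotide background. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
stated model, not performance on any particular real dataset.

## Numerical choices and degenerate inputs

- Score snapping at 1e-9 as above; an all-uniform (uninformative) PWM
  scores 0 with a warning rather than dividing by zero.
- OLS via numpy least squares; rank-deficient design submatrices are
  rejected (`CollinearityError`) and treated as worse than any valid fit
  during search.
- RSS is floored at 1e-12 inside log-likelihood terms so noiseless
  interpolating fits win without −∞ arithmetic; ties break toward
  smaller subsets, then lexicographic feature order.
- Fold changes use pseudocount ε = 1.0 throughout.
- Promoters shorter than a motif yield an empty hit list, not an error.
- `correlate` reports zero-variance input as an error, never NaN.

## Known limitations

- The calibrated selection penalty assumes roughly independent candidate
  entry tests; strongly collinear PWM features (near-duplicate motifs)
  share credit and can split selection frequency between them.
- Exhaustive search cost grows combinatorially; beyond the subset budget
  the forward fallback is greedy and can miss jointly-informative
  feature pairs that are individually weak.
- The DE engine is a replicate-level Welch test, adequate for the
  pipeline's thresholding contract but not a negative-binomial count
  model; with very few replicates its power is limited.
- Regularized regression, interaction terms and epigenomic covariates
  are out of scope.
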