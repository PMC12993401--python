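# Methods

## Scope and data model

The pipeline starts at parcellated ROI time series: one T×N matrix per
subject per session (baseline, follow-up), plus an atlas table classifying
each ROI as cerebral or cerebellar. Everything upstream — acquisition,
realignment, normalization, denoising, hemisphere flipping for
right-treated patients — is out of scope and assumed already applied. The
full-scale design the package emulates is 37 subjects × 2 sessions, 273
ROIs (246 cerebral + 27 cerebellar), 250 time points per scan.

## Connectivity and thresholding

Functional connectivity is the Pearson correlation between ROI time series,
Fisher r-to-z transformed for variance stabilization, with negative values
set to zero (the physiological meaning of negative correlations is
contested, and the binarized analysis only ranks positive couplings). The
diagonal is zero. Off-diagonal |r| = 1 cannot occur on noisy data; it is
clipped to 1 − 1e−7 before `artanh` with a warning so z stays finite.

Binarization is density-based: at sparsity s the K = round(s·N(N−1)/2)
strongest connections become edges. Choices the literature leaves open, and
how they are fixed here:

- **Rounding**: nearest integer, ties half-up. Any consistent rule works;
  this one is explicit and testable (e.g. N=273, s=0.15 → 5,569 edges).
- **Tie-breaking at the cut**: total order (weight desc, row asc, col asc),
  so output is identical across runs and platforms.
- **Nestedness**: one shared descending ordering of the positive
  connections serves the whole grid, so E(s₁) ⊆ E(s₂) for s₁ < s₂ by
  construction.
- **Too few positive connections**: all positive connections are kept and
  the achieved density is recorded; AUC integrates over the requested grid
  with the achieved graphs.
- **Admissibility**: average degree must exceed 2·ln N (natural logarithm
  — the conventional criterion's own arithmetic at N=273 gives 11.22 only
  for ln) and σ > 1.1 across the grid; the report lists failing densities
  rather than aborting.

## Graph metrics

All metrics are computed on binary graphs. Cp is Watts–Strogatz clustering
(mean over nodes of 2T_i/(k_i(k_i−1)), 0 for degree < 2). Lp is the mean
shortest-path length over ordered pairs; on disconnected graphs infinite
pairs are excluded and a flag is set (common toolbox behaviour, keeps Lp
finite at low densities). Eg is the mean of 1/d over ordered pairs with
unreachable pairs contributing 0, so it handles disconnection natively;
Eloc is the mean over nodes of Eg of the neighbourhood subgraph. Nodal
efficiency is the per-node row mean of 1/d. Betweenness is
fraction-of-shortest-paths (Brandes) betweenness, normalized by
(N−1)(N−2)/2; the C implementation in python-igraph is used, validated in
the test suite against exhaustive path enumeration. Distances come from a
numba breadth-first-search kernel (cross-checked against scipy.csgraph and
networkx in tests).

Curves over the grid are summarized by the trapezoidal AUC. Rectangle
integration would differ only by a near-constant scale factor at step 0.01;
trapezoid is exact for piecewise-linear curves and refinement-invariant.

## Null models and small-worldness

Random references preserve the degree sequence exactly via Maslov–Sneppen
double-edge swaps (rejecting self-loops and multi-edges). Defaults:
100 nulls in the full-scale preset, 20 in the test preset, 10 attempted
swaps per edge; replicate simulations use 3 nulls and 5 swaps per edge
(the normalized ratios only enter those experiments through means whose
noise is symmetric across sessions). γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩,
σ = γ/λ exactly; null Lp uses the same finite-pairs convention as the real
graph. Each (subject, session, density) slice gets its own ensemble seeded
deterministically from (master seed, subject, session, density), so reruns
are bit-identical. The degenerate case ⟨Cp_null⟩ = 0 (extreme sparsity)
yields γ = NaN with a warning rather than a crash.

## Modular analysis

The group graph is the element-wise mean of baseline Fisher-z matrices
binarized at density 0.15 (the sparsest density with low risk of spurious
connections). Community detection is a deterministic agglomerative greedy
modularity optimizer: start from singletons, repeatedly merge the community
pair with the largest positive ΔQ, ties broken toward the smallest
community indices, stop when no positive gain remains. "Modified greedy
optimization" is under-specified in the toolbox literature; this CNM-style
variant is validated against exhaustive partition search on small graphs
and against planted block models (NMI ≥ 0.9). Q ≥ 0.3 is flagged as
non-random community structure, following convention. The partition is
estimated once from baseline and held fixed for both sessions.

Within/between-module "connectivity" is counted as binary edge counts at
density 0.15 against the fixed partition. Magnitudes in published tables of
this analysis type (intra-module totals near s·N(N−1)/2) are consistent
with edge counts rather than z-value sums, so counts are used. Participation
coefficients (1 − Σ_m (k_im/k_i)², 0 for isolated nodes) are computed at
the 0.15 slice only, since they require the partition's density; the other
nodal metrics entering the restricted analysis are AUC-over-grid,
consistent with the whole-brain nodal analysis.

## Statistical plan

Per paired sample, a Shapiro–Wilk test on the differences (α = 0.05)
selects paired t (p ≥ 0.05) or Wilcoxon signed-rank. Wilcoxon drops zero
differences (Wilcoxon's original convention), uses the exact null
distribution for n ≤ 25 without ties and the normal approximation with
continuity correction otherwise. Identical sessions short-circuit to
p = 1 (no evidence) with a degeneracy flag.

Families and corrections mirror the study design:

- **Global AUC metrics** (σ, γ, Cp, Eg, Eloc expected ↑; Lp, λ, Q expected
  ↓): one-tailed, uncorrected. The direction table is fixed a priori, data
  independent, and logged with every run. The direction for Q follows the
  stated hypothesis that treatment reduces network segregation.
- **Whole-brain nodal AUCs**: two-tailed, BH-FDR across nodes within each
  metric (family scope per metric, noted explicitly since conventions vary).
- **Module-pair counts**: two-tailed, BH-FDR across the between-module
  pairs and, separately, the within-module family; trend flags at
  uncorrected p < 0.05.
- **Restricted nodal family**: nodes of the modules implicated by
  trend-level between-module changes; BH-FDR within that node set per
  metric (degree, nodal efficiency, betweenness AUC; participation at 0.15).
- **Clinical correlations**: Spearman (midranks, two-sided) of per-subject
  changes in global metrics vs. changes in tremor scores, and of significant
  restricted betweenness changes vs. clinical changes and trending
  module-pair count changes. Skipped with a notice when no clinical table
  is supplied.

BH adjustment is the standard step-up procedure (via statsmodels),
order-preserving and verified against the hand rule in tests.

## Synthetic cohort generator

No generative model exists for this kind of study (the analyses are run on
real fMRI); the generator uses the simplest structure that reproduces what
the analysis assumes: a block-correlated multivariate normal. ROIs belong
to K planted modules; the latent correlation is `rho_within` inside modules
and `rho_between` across. At follow-up, designated module pairs gain
`delta_rho` on their between-block and designated hub ROIs gain `delta_hub`
on all their cross-module entries, capped just below `rho_within`; the
matrix is projected to the nearest positive semi-definite correlation
matrix (eigenvalue clipping, diagonal rescale) when needed, and every
latent matrix is verified PSD before sampling. Sessions are T independent
draws with covariance R + noise_sd²·I.

Defaults (units are correlation unless noted):

| parameter | default | rationale |
| --- | --- | --- |
| scaled design | 20 subjects, 90 ROIs (6×15), T=150 | desk-minutes emulation of the 37/273/250 study design (available as the `paper` preset with module sizes 31/33/77/18/69/45) |
| rho_within | 0.5 | strong but imperfect within-network coupling typical of resting-state FC |
| rho_between | 0.1 | weak background cross-network coupling |
| delta_rho | 0.15 | planted between-module effect, large enough to be a clear ground truth |
| delta_hub | 0.15 | hub cross-module boost, chosen equal to delta_rho as a comparable effect size |
| noise_sd | 0.5 | observation noise; attenuates observed correlations by 1/(1+noise_sd²) = 0.8 |
| subject jitter | ±0.03 uniform on rho levels | between-subject variance without destroying block structure; drawn once per subject and shared by both sessions, so null cohorts are exchangeable across sessions |

The generator emulates modular FC, hubs and a paired session effect. It does
**not** model hemodynamics, temporal autocorrelation, motion or physiological
noise, scanner drift, or spatial smoothness — so passing tests demonstrate
correctness of the analysis chain and its statistical calibration under the
assumed structure, not robustness to real-fMRI artefacts. Clinical scores
are generated with a per-subject improvement fraction (mean 0.65) applied to
the treated side only, matching the convention of averaging per-subject
percent improvements.

## Simulation experiment sizes

The calibration experiments (`tremornet.replication`) use scaled problem
sizes chosen to keep hundreds of replicates within desk minutes on one CPU:
the type-I experiment runs 200 null cohorts (20 subjects, 90 ROIs, grid
0.10–0.40 step 0.10, 3 nulls per slice); the recovery experiment runs 50
planted-effect cohorts (grid 0.10–0.40 step 0.05, no null ensembles, since
recovery only needs nodal AUCs and module counts). The acceptance band for
the pooled type-I rate, [0.02, 0.085], is the binomial sampling band around
the nominal 0.05 after allowing for the strong correlation among the eight
global metrics within a cohort (effective sample well below 200×8).

## Known limitations

- The greedy optimizer is agglomerative only (no fine-tuning pass); its Q
  is the contract, validated against exhaustive search at small n.
- Lp on disconnected graphs is a finite-pairs average; comparisons across
  densities mix connected and disconnected regimes at the sparse end.
- Weighted-network variants, consensus clustering across densities, and
  multi-resolution modularity are out of scope.
- The full-scale (`paper`) preset with 100 nulls across the 46-density grid
  is hours of compute on one CPU; the scaled preset is the default for
  development and testing.
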