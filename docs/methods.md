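# Methods

This note records the models, conventions and numerical choices behind
`sitevar`, and what the synthetic validation does and does not establish.

## Profiles

**Structure.** Site indexing is 1-based ordinal along the chain, decoupled
from author residue numbers; the first-listed alternate location and the
first model of a multi-model file are used; selenomethionine is read as
methionine, other nonstandard residues are skipped with a warning. WCN is
`Σ_{j≠i} r_ij⁻²` over Cα–Cα distances; CN counts Cα within the cut-off
*inclusively* (the boundary case has measure zero for real coordinates;
inclusivity fixes determinism). ASA uses the Shrake–Rupley construction:
960 quasi-uniform test points (golden-spiral layout, deterministic) on each
atom's solvent-expanded sphere (vdW + 1.4 Å probe); a point is accessible
when outside every other expanded sphere. Doubling the point count changes
no site by more than 2% (tested), and agreement with an independent
implementation (biotite) is within a few percent; absolute values can
differ from DSSP by a few percent because DSSP's slice algorithm differs.
Van der Waals radii are the Bondi element values (C 1.70, N 1.55, O 1.52,
S 1.80 Å). For Cα-only models each site becomes a single 3.0 Å pseudo-atom
and the profile is flagged `pseudo_atoms`. RSA divides by the Rose (1985),
Miller (1987) or Tien (2013, theoretical) max-ASA tables and is clamped to
[0, 1] (extended termini can exceed the tabulated maxima; the clamp count
is logged).

**Sequence.** Gaps are excluded from column frequencies and from
sum-of-pairs terms; a column with fewer than two non-gap residues is
missing (NaN), and NaNs propagate through smoothing and are dropped
pairwise in correlations. A documented switch (`gap_score_zero`) instead
scores gap-containing pairs as zero similarity. The JTT250 similarity
matrix is Biopython's JONES matrix; KBSP normalizes it as
`M'_ab = M_ab / √(M_aa · M_bb)` (unit diagonal), and VTSP uses the min-max
rescaling *of that normalized form* onto [0, 1]. Rescaling the
unit-diagonal form (rather than the raw log-odds) keeps self-similarity
exactly 1, so both sum-of-pairs scores equal 1 precisely on conserved
columns while the min-max bounds (min 0, max 1 attained) still hold — the
one construction that satisfies every stated property at once. VTSP
sequence weights are each row's mean distance (1 − fractional identity) to
the others; an all-identical alignment degenerates to equal weights.

**Homolog filtering.** Identity and overlap come from pairwise global
alignment with free end gaps (BLOSUM62, gap open 11 / extend 1); identity
is matches over the shorter sequence (the CD-HIT convention — this lets a
short fragment with perfect local identity be classified by the overlap
rule rather than as a near-duplicate), overlap is the aligned span on the
query over the query length. Removal rules: identity > 95%, length < 60%
of the query, overlap < 10%. The cap at 300 representatives uses greedy
incremental clustering ordered by closeness to the query, lowering the
threshold from 100% in 1% steps until the representative count fits, then
topping up with the remaining query-proximal sequences so exactly 300
survive when supply allows.

## Rates and trees

The substitution model is JTT (Jones et al. 1992 exchangeabilities and
frequencies, hard-coded), assembled as a reversible rate matrix scaled to
one expected substitution per site per time unit; P(t) comes from the
symmetric eigendecomposition of Π^{1/2}QΠ^{-1/2}, with rows clipped at 0
and renormalized against rounding. Pairwise distances are Poisson-corrected
p-distances over shared non-gap columns, capped at 3.0 for p ≥ 0.95 (a
documented alternative would be ML distances under JTT). NJ is Saitou–Nei
with negative branch lengths clamped to zero and the excess shifted to the
sibling so each cherry keeps its joint length; ties in the Q matrix break
toward the lowest index. UPGMA is average linkage with merge heights
halved.

CS fits the discrete-gamma shape α by bounded 1-D maximization of the
marginal log-likelihood over [0.05, 20] (tolerance 1e-4; a boundary hit is
warned and used). K = 16 equal-probability categories with conditional-mean
rates (computed from the regularized incomplete gamma function; the
category mean is exactly 1). Site rates are posterior means over
categories, then divided by the over-sites mean so the profile averages
to 1 — a ratio-to-average normalization, deliberately not a z-score.
Likelihoods use per-site rescaling so 300-taxon alignments stay in range;
gaps are missing data (all-ones partials). ET weights each partition level
n = 1..M−1 by 1/n, splitting the current group with the greatest merge
height first (ties break on lexicographic leaf names for determinism).

## Comparison statistics

All reported correlations — including those inside the variance
partitioning — use profiles smoothed with a centered window of 3 (truncated
at the termini, NaN-aware) and sign-oriented so that packed or conserved
sites score low; orientation is applied once, and a second application is
an error. The three tests are one-sided in the direction "predictor 1
better", since the hypotheses are directional; binomial ties are dropped
(sign-test convention); significance requires the worst P value < 0.01,
which is the pipeline's only multiple-testing guard (none further is
applied, by design). Variance partitioning computes R² from the three
pairwise correlations in closed form; unique contributions are the R²
increments from adding each variable; negative uniques (suppressor
configurations) are reported with a warning, not clamped; exactly collinear
predictors are an error. Dataset summaries report both SD and SEM of the
per-protein values, and percentages are averaged per protein.

## Synthetic data

The generator emulates the study conditions at desk scale: 30 proteins of
150 sites with 60-taxon MSAs (defaults chosen once, before any results were
inspected). Structures are self-avoiding random Cα chains (bond 3.8 Å,
non-consecutive separation ≥ 4.0 Å) confined to a sphere of radius
3·n^{1/3} Å — the density of a compact globule, giving a realistic spread
of packing densities (90th/10th WCN percentile ratio ≈ 1.6). Site rates
follow the mechanistic premise of a linear rate–packing relationship:
r_i ∝ max(0.01, 1 + slope·(⟨WCN⟩ − WCN_i)/sd(WCN) + N(0, noise)), slope 1,
noise SD 0.3, normalized to mean 1. Trees are Yule with all branch lengths
scaled so every root-to-tip path is 1.0 expected substitutions — a
divergence at which 60 sequences carry strong but not saturated signal.
MSAs are simulated under JTT with per-site branch scaling and no indels
(profiles are computed on the query mapping, so indels would add nothing).
The simulation starts at the query leaf with the structure's own sequence
and evolves outward over the tree as an undirected graph — equivalent in
distribution for a reversible model, and it makes structure sites and
alignment columns identical by construction, so in the mirrored control the
RSA that drives the rates is the very RSA the pipeline measures. Per-protein
seeds are `seed + 1000·index`, so batches are reproducible under any
execution order.

What the benchmark shows: the pipeline recovers imposed rates (Spearman
≈ 0.94 at 60 taxa, improving with taxon count), identifies the true
structural driver in both the packing-driven and the exposure-driven
scenario, and decomposes variance correctly. What it does not show:
absolute correlation levels comparable to real proteins. Real enzymes give
structure–rate correlations near 0.6; the synthetic globules give ≈ 0.9
because the imposed rate law is cleaner than real mutation–selection
dynamics, pseudo-atom ASA is noise-free, and alignments have no indels or
composition drift. Directional conclusions transfer; magnitudes do not.
Likewise the optimal CN cut-off on 150-site globules (≈ 10–11 Å) is smaller
than on real proteins, whose larger diameter shifts the scan optimum
upward.

## Known limitations

- Single chains only; no mmCIF; multimeric assemblies out of scope.
- ASA is not DSSP-identical (different algorithm, heteroatoms excluded).
- CS mirrors the cited empirical-Bayes defaults (K = 16, JTT, NJ input
  tree) but not any particular Rate4Site build; rank-level results are
  robust to this, absolute rates less so.
- The homolog-filter clustering is a deterministic stand-in for CD-HIT,
  not a reimplementation of its word-filter heuristics.
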