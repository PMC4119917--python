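# sitevar

What structural property of a protein site determines how fast it evolves —
how tightly the site is packed, or how exposed it is to solvent? `sitevar`
implements, as a tested Python package, the complete site-level analysis
behind that question: structural profiles from coordinates, sequence
variability profiles from alignments, a paired statistical battery for
comparing predictors, and a variance partitioning that splits the explained
variance of evolutionary rate into the unique and redundant contributions of
packing density and solvent accessibility. Everything is validated
end-to-end on synthetic structure-coupled sequence evolution, so no
structure downloads or homology searches are required.

It is written for structural bioinformaticians and molecular evolution
researchers who want either the individual profile calculators or the whole
comparison pipeline.

## The quantities

Per-site **structural profiles** for a chain of N residues:

- **WCN** (weighted contact number, local packing density):
  `WCN_i = Σ_{j≠i} 1 / r_ij²` over Cα–Cα distances `r_ij` (Å⁻²);
- **CN(r₀)**: number of other Cα within a cut-off radius r₀ (scanned
  9–30 Å);
- **ASA**: Shrake–Rupley accessible surface area with a 1.4 Å water probe;
- **RSA** = ASA / maxASA(amino acid), under the Rose, Miller or Tien
  max-ASA tables (RSA^R, RSA^M, RSA^T).

Per-site **sequence variability profiles** from an MSA with a designated
query row:

- **CS**: site-specific relative evolutionary rate by empirical Bayes — NJ
  tree from Poisson-corrected distances, Felsenstein pruning under the JTT
  model, discrete-gamma rate prior (16 equal-probability categories, shape
  fitted by maximum likelihood), posterior-mean rates normalized to mean 1;
- **ET**: real-valued evolutionary trace, `ET_i = 1 + Σ_n (1/n) Σ_g s_ig`,
  summing within-group column entropies over the nested n-group partitions
  of a UPGMA tree (branch lengths ignored);
- **KBSP / VTSP**: sum-of-pairs conservation over a normalized JTT250
  similarity matrix, the latter with sequence weights that damp redundancy;
- **EN**: Shannon entropy `EN_i = −Σ_a f_ia ln f_ia` of the column's
  amino acid frequencies.

All profiles are smoothed (window 3) and sign-oriented (packed/conserved =
low) before Pearson or Spearman correlation. Two predictors x₁, x₂ of a
reference y are compared over a protein dataset with a one-sided paired
t-test, a binomial test on the win proportion, and Wilcoxon's signed-rank
test; the comparison counts as significant only when the *worst* of the
three P values is below 0.01. The bivariate fit y ~ x₁ + x₂ is decomposed
as

    R² = ρ²(y, x₁ or x₂) + ρ²(y, x₁ | x₂) + ρ²(y, x₂ | x₁)

where the squared semipartial correlations are the unique contributions of
each predictor and the first term is their redundancy.

## Worked example

The benchmark generates compact self-avoiding Cα globules, imposes site
rates that decrease linearly with WCN (noise SD 0.3), simulates 60-sequence
MSAs along Yule trees under the JTT model, and then runs the full analysis
blind to the truth:

```bash
python analysis/03_wcn_benchmark.py
```

prints

```
30 proteins, packing-driven rates:
  mean rho(CS, WCN)   = 0.930
  mean rho(CS, RSA_T) = 0.844
  delta = +0.085, WCN wins in 100% of proteins, worst P = 9.3e-10 (significant)
  variance partition: total R2 0.869; unique WCN 17.9% vs unique RSA 0.5% of explained variance
  rate recovery: mean Spearman(CS, truth) = 0.940
```

The inferred rates track the imposed ones (Spearman 0.94), the true driver
(packing) beats solvent accessibility under the worst-P rule, and its unique
share of the explained variance dwarfs that of RSA. The mirrored control
(`analysis/04_rsa_control.py`), whose rates follow RSA instead, flips every
one of those outcomes (delta −0.098, unique RSA 20.1% vs unique WCN 0.2%),
showing the pipeline has no built-in preference for packing density.
`analysis/01_simulate_dataset.py` reports the generator diagnostics and
`analysis/02_cn_cutoff_scan.py` the CN cut-off scan; all tables land in
`results/`.

The library surface mirrors the pipeline: `read_pdb` / `read_alignment` /
`read_newick` (module `sitevar.io`, `sitevar.tree`), `compute_wcn` /
`compute_cn` / `compute_asa` / `compute_rsa` / `scan_cn_cutoff`
(`sitevar.structure`), `compute_entropy` / `compute_kbsp` / `compute_vtsp`
/ `filter_homologs` (`sitevar.sequence`), `build_nj_tree` /
`build_upgma_tree` / `compute_cs` / `compute_et` (`sitevar.phylo`),
`smooth_profile` / `orient_profile` / `correlate` / `compare_predictors` /
`variance_partition` (`sitevar.stats`), and the generator in
`sitevar.synth`. A thin CLI (`sitevar profiles|compare|partition|simulate|
benchmark`) wraps the same functions.

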