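# ironforms

Quantification of the molecular iron forms found in cortical brain tissue,
combining three experimental windows on the same specimen:

* **MRI relaxometry** — the effective transverse relaxation rate R2\* from a
  multi-gradient-echo magnitude series, `y(TE) = A e^(-TE·R2*)`, summarized
  per region of interest by its median;
* **EPR spectroscopy** — non-heme, high-spin rhombic Fe(III) (the g′ = 4.3
  signal) quantified by simulating the S = 5/2 spin-Hamiltonian powder
  spectrum, `H = gμ_B B·S + D(S_z² − S(S+1)/3) + E(S_x² − S_y²)`, fitting
  only an amplitude plus a linear baseline to each measured spectrum, and
  comparing double integrals with an Fe-EDTA reference of known
  concentration;
* **SQUID magnetometry** — isothermal remanent magnetization (IRM) curves
  fitted to the Langevin model
  `IRM(H) = M_s f [coth x − 1/x] + B`, `x = μ_p H / (k_B T)`, at 100 K
  (magnetite/maghemite, M_s = 84 emu/g) and 5 K (ferrihydrite, the ferritin
  core mineral, M_s = 0.62 emu/g).  The 5 K particle moment maps to the
  ferritin iron loading factor through Néel's relation
  `μ_p = 5.92 μ_B · LF^α` (α = 0.5–0.6), and the loading ratio is
  FLR = 100·LF/4500.

On top of the per-subject measures sits the cohort statistics layer used to
compare an Alzheimer's-disease group with controls: log transforms, an
automated χ² outlier screen, Student's t and Brown–Forsythe variance tests,
demographics tests, the Spearman correlogram, the Fisher-z studentized
difference for comparing a correlation between independent groups
(`zr = ½ ln((1+ρ)/(1−ρ))`,
`z_diff = (zr₂ − zr₁)/√(1/(N₁−3) + 1/(N₂−3))`), rank-based partial
correlation, and Braak-stage stratification.

Because no raw post-mortem cohort of this kind is publicly deposited, the
package ships a first-class **synthetic cohort generator**: a Gaussian
copula reproduces the published group means/SDs and Spearman correlation
structure, and per-subject raw signals (echo stacks with Rician noise, IRM
curves and EPR spectra with Gaussian noise) are synthesized from each
subject's ground truth so that every fitting stage has a parameter-recovery
test surface.

Intended users: physicists and image analysts working on tissue iron
quantification, and anyone needing a reproducible reference implementation
of these estimators.

## Worked example

Comparing the ferrihydrite–Fe(III) Spearman coefficient of an AD group
(ρ = −0.629, N = 18) against controls (ρ = −0.908, N = 11):

```python
>>> from ironforms.stats import compare_correlations
>>> cc = compare_correlations(-0.629, 18, -0.908, 11)
>>> print(f"z_diff = {cc.z_diff:.3f}, p = {cc.p:.3f}")
z_diff = -1.773, p = 0.076
```

The two coefficients differ by 1.77 standard errors on the Fisher-z scale —
suggestive but not significant at the 0.05 level.

A full synthetic run — generate a 22 + 14 cohort, synthesize raw signals,
fit all three modalities, assemble the panel and test it:

```bash
ironforms run-all --seed 1 --outdir run1
```

`run1/stats_tests.csv` then contains (Student's t on transformed data):

```
        variable  statistic        p
          r2star   2.784568 0.008695
             fe3   1.656406 0.106841
    ferrihydrite   2.310543 0.027055
       magnetite  -0.020578 0.983703
magnetite_moment   3.628621 0.001126
             flr   1.628954 0.112555
```

i.e. the recovered pattern matches the generating cohort structure: R2\*,
ferrihydrite concentration and the magnetite particle moment separate the
groups, while Fe(III), magnetite concentration and the ferritin loading
ratio do not.  `stats_report.json` carries the correlograms, the group
correlation comparisons and the pooled partial correlations, and
`manifest.json` records the seed and every stage output; reruns with the
same config are byte-identical.

Every stage is also exposed individually (`ironforms simulate`, `r2star`,
`epr-quant`, `irm-fit`, `stats`), communicating only through NIfTI / CSV /
JSON-sidecar files, so the stages can run as separate processes.

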