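# Methods

This note documents the models implemented in `ironforms`, the defaults and
units of every parameter that matters, the numerical choices, and what the
synthetic cohort can and cannot establish about real data.

## R2\* relaxometry

Each voxel of a multi-gradient-echo magnitude series is modeled as a pure
mono-exponential, `y(TE) = A e^(-TE·R2*)`, with no baseline term.  Echo
times default to 12.5, 23.3, 33.9 and 44.6 ms.  The default fit is linear
regression of `log y` on TE weighted by `y²` — the first-order correction
for the variance inflation of the log transform — because with only four
echoes a fully nonlinear fit gains little and is fragile at low SNR; an
optional Levenberg–Marquardt refinement of the exponential itself is
available (`method="nonlinear"`), and the two agree to better than 0.5 % on
noiseless data.  Voxels with a non-positive sample at any echo are flagged
invalid rather than raising; negative fitted rates (possible under noise)
are retained but flagged.  An ROI is summarized by the **median** R2\* over
its valid voxels, which is far less sensitive than the mean to the exact
outline and to outlier voxels.

Raw magnitude data are fitted as-is.  Magnitude (Rician) noise biases the
measured signal upward where SNR is low — here the latest echo — so R2\* is
slightly underestimated at low SNR: at an acquisition SNR of 20 (channel sd
= mean ROI signal across echoes / 20) the median bias is about −1 % with a
per-voxel median absolute error just under 5 %; the ROI median inherits
only the bias.  No Rician bias correction is applied.

## EPR of rhombic Fe(III)

High-spin Fe(III) (S = 5/2) in a rhombic ligand field is described by

    H = μ_B B·g·S + D(S_z² − S(S+1)/3) + E(S_x² − S_y²)

with one fixed parameter set for all samples: D = 20.96 GHz,
E/D = 0.3324 (essentially maximal rhombicity), g = (1.83, 1.998, 2.0151)
and Gaussian g-strain widths (0.574, 0.129, 0.0197), microwave frequency
9.4859 GHz, temperature 12 K.  At maximal rhombicity the middle Kramers
doublet produces the nearly isotropic effective g′ = 4.3 resonance at
B = hν/(g′μ_B) ≈ 157.6 mT.

The powder simulation:

* orientations on a deterministic spherical Fibonacci grid (default 400),
  folded onto one octant by the D2h symmetry of the Hamiltonian —
  reproducible with no quadrature tables; doubling the grid changes the
  double integral by < 1 %;
* resonance fields located by bracketing sign changes of
  `(E_j − E_i) − hν` on a 200-point field grid and refining each bracket
  with 30 bisection steps on the exact 6×6 eigenvalues (≈ 1e-6 mT bracket
  width; verified to < 0.1 mT against an independently coded dense
  eigenvalue scan);
* transition intensity `|⟨i|B₁·g·S|j⟩|²` averaged over two directions
  perpendicular to B₀, multiplied by the Boltzmann population difference at
  12 K (D ≈ 1 K, so inter-doublet populations matter even though
  intra-doublet ones are nearly equal) and the frequency-to-field factor
  `1/|d(E_j−E_i)/dB|`;
* g-strain mapped to first order onto a per-transition Gaussian field width
  `σ_B² = Σ_k (∂B_res/∂g_k)² σ_gk²`, the derivatives obtained analytically
  from the Hellmann–Feynman theorem; a 1 mT intrinsic width is added in
  quadrature so strain-free transitions are not numerical sticks.  The 6
  G_pp modulation amplitude (0.6 mT) is *not* convolved: it is small
  against the strain-dominated linewidths.

Quantification holds the spin-Hamiltonian parameters fixed (one template
serves all samples, which is what makes double-integral comparison
meaningful) and fits only a non-negative amplitude plus a linear baseline
by least squares.  The Fe(III) concentration is

    c = (scale · ∬template / ∬reference) · c_ref · m_ref / m_sample,

i.e. double-integral comparison against an Fe-EDTA reference of known
concentration measured under matched conditions; a temperature mismatch
between sample and reference triggers a warning (no Curie-law correction is
applied).  Fields are millitesla internally; gauss is accepted on input
(1 mT = 10 G).  The default simulation axis, 50–350 mT, brackets the
g′ = 4.3 line; sweep parameters of real acquisitions vary, and the template
is resampled onto the measured axis when needed.

## SQUID / IRM magnetometry

IRM curves (remanent moment per dry gram versus applied field, measured
after field application at fixed temperature) are fitted to the Langevin
model with the temperature and saturation magnetization fixed:

    IRM(H) = M_s f [coth x − 1/x] + B,   x = μ_p H / (k_B T).

All internals are CGS-Gaussian (gauss, emu, erg; μ_B = 9.274×10⁻²¹ erg/G),
in which x is dimensionless; tesla input is converted at the boundary.
Free parameters: the mass fraction `f`, the mean particle moment `μ_p`
(reported in Bohr magnetons) and a constant background `B` absorbing
residual fields.  Start values: `μ_p` from the field at half-saturation
(x ≈ 1.6), `f` from the high-field plateau.  A single mean moment is
fitted, not a size distribution — one moment per sample is what the
downstream statistics consume.  A fit driving `f` negative is refit with
`f` clipped at zero and flagged; non-convergence is flagged, never raised.

Role assignment: the 100 K curve quantifies magnetite/maghemite
(M_s = 84 emu/g, appropriate for blocked particles ≳ 25–35 nm; IRM cannot
distinguish magnetite from maghemite), reported in ng per dry gram; the
5 K curve quantifies ferrihydrite (M_s = 0.62 emu/g), reported in µg per
dry gram.  Weak 100 K signals are screened: a curve is usable only if its
peak-to-peak *moment* (amplitude × dry mass) is at least 4× the instrument
noise floor (default 1×10⁻⁸ emu, RSO-probe sensitivity at 0–2.5 T); ties
count as usable.  Discarded curves report zero magnetite concentration and
a *missing* moment, which downstream statistics exclude pairwise.

Ferritin loading: inverting Néel's relation gives
`LF = (μ_p/5.92)^(1/α)` iron atoms per core and `FLR = 100·LF/4500` % of
capacity.  α defaults to 0.5 (the low end of the quoted 0.5–0.6 range,
giving the conservative, larger LF for a given moment and making the
moment→LF map exactly quadratic); it is exposed everywhere and restricted
to [0.5, 0.6].  LF beyond the 4500-atom capacity is capped with a warning.

## Cohort statistics

* Transforms before mean testing: Fe(III) → log₁₀(x); magnetite →
  log₁₀(x + 100), the offset accommodating exact zeros from the discard
  rule.  Correlations are computed on *untransformed* values (Spearman is
  invariant to monotone transforms, so this choice only matters for the
  mean tests).
* Outlier screen: the χ² statistic of the most extreme point,
  `(x_ext − x̄)²/s²`, referred to its **max-calibrated** null distribution
  via the exact Grubbs relation to the Student t distribution (two-sided,
  Bonferroni factor 2n), flagged at 0.05 and iterated at most twice.  The
  naive χ²₁ reference would ignore the maximization over n points — it is
  bounded above by (n−1)²/n, so at n = 4 it could never flag anything, and
  at large n it over-flags; the max-calibrated version has a family-wise
  flag rate of ≈ 5 % on clean normal samples at any n.  Points are flagged,
  never silently deleted.
* Mean tests: Student's pooled-variance t on transformed data by default,
  with the Welch variant always reported alongside (which variance
  convention real analyses used is rarely recoverable; reporting both costs
  nothing).  Variance test: Brown–Forsythe — one-way ANOVA on absolute
  deviations from each group's median; its true null rejection rate is
  slightly below nominal at small n (≈ 0.040 at n = 22/14, ≈ 0.047 at
  n = 100/100).  Demographics: Mann–Whitney U for age, χ² contingency for
  sex.
* Correlogram: Spearman ρ with two-tailed p from the t approximation,
  pairwise-complete observations; below n = 10 the p-value comes from full
  permutation enumeration instead.  Constant columns and pairs with < 4
  complete observations report NA.
* Correlation comparison: exact Fisher-z studentized difference with
  two-tailed normal p.  It agrees with a group-label permutation null
  within Monte-Carlo error on synthetic data.
* Partial correlation: first-order recursion on Spearman coefficients
  (rank-based, matching the headline correlations; Pearson via flag), p
  from t with n − 3 df, computed on the pooled groups.
* Braak stratification: controls with stage ≤ 3 pooled into one stratum;
  AD strata 4, 5, 6; descriptive means/medians only, no trend test.

## Synthetic cohort generator

Each diagnostic group is drawn from a Gaussian copula.  Marginals (defaults
are the published group summaries; ferritin-loading and magnetite-moment
marginals have no published tabulated summaries, so their defaults
were chosen once to place control FLR below ~50 % with AD shifted upward
but overlapping, and AD magnetite moments larger than control — ~6×10⁴ vs
~2.5×10⁴ μ_B):

| variable            | family                    | AD (mean ± sd)    | control           |
|---------------------|---------------------------|-------------------|-------------------|
| R2\* (ms⁻¹)          | truncated normal at 0     | 0.033 ± 0.005     | 0.028 ± 0.004     |
| Fe(III) (µg/g ww)   | lognormal                 | 6.74 ± 3.48       | 5.29 ± 3.66       |
| ferrihydrite (µg/g) | truncated normal at 0     | 381.12 ± 178.97   | 240.84 ± 98.02    |
| magnetite (ng/g)    | log₁₀(x+100) normal, clipped at 0 | 118.83 ± 125.87 | 121.03 ± 123.11 |
| magnetite μ_p (μ_B) | lognormal                 | 60000 ± 30000     | 25000 ± 12000     |
| FLR (%)             | truncated normal [0,100]  | 36 ± 14           | 28 ± 10           |

Latent parameters of every family are solved (closed form for lognormal,
numerically otherwise) so the *transformed* distribution has exactly the
target mean and sd; the clip at zero for magnetite emulates the point mass
created by the SNR discard rule.  LF follows deterministically from FLR,
and the 5 K particle moment from LF via Néel's relation, so the panel is
mutually consistent.

Target Spearman correlations are the published significant pairs
(Fe(III)–ferrihydrite, Fe(III)–FLR, ferrihydrite–FLR in both groups;
magnetite–ferrihydrite in AD only); unreported pairs are set to 0 — the
joint distribution beyond pairwise rank correlations is not identified by
the published summaries, and the Gaussian copula is this package's choice.
A target Spearman ρ maps to a latent Pearson correlation 2·sin(πρ/6); the
matrix is repaired to the nearest positive-semidefinite correlation by
eigenvalue clipping, and a repair that moves any entry by more than 0.05 is
a hard error (the published matrices need no repair).

Marginal values are drawn, by default, as randomized Latin-hypercube
quantiles reordered to the ranks of the correlated Gaussian scores
(Iman–Conover).  This makes finite cohorts reproduce the specified
means/SDs with negligible Monte-Carlo error (the sample SD of a heavy-
tailed lognormal would otherwise wander by several percent even at
n = 10⁴) while leaving the rank-correlation structure exactly that of an
iid Gaussian-copula sample.  When marginal sampling variability is itself
the object of study — power or type-I calibration simulations — use
`marginal_sampling="iid"`.

Braak stages are assigned within each group's admissible range (controls
0–3, AD 4–6) by rank of a latent severity score (mean latent z of R2\*,
ferrihydrite and magnetite moment), so the variables that separate the
groups also trend with stage, as a disease-staging covariate should; a
uniform-random rule is available.

Raw signals: echo stacks place the subject's true R2\* in a central
rectangular ROI over a slower-decaying background, with Rician noise
(channel sd quoted as a fraction of the mean ROI signal across echoes —
magnitude-detector physics); IRM curves follow the Langevin forward model
on a 30-point log-spaced 10 G – 2.5 T grid with additive Gaussian noise
(flux-detection physics); EPR spectra scale the simulated template so the
double integral encodes the subject's Fe(III) relative to the reference,
plus Gaussian noise.  Default noise levels for a "realistic" run: MRI SNR
20, SQUID 1 % of the saturation signal, EPR 1 % of the template peak.

**What passing tests do and do not show.**  Noiseless round trips prove the
estimators invert the forward models exactly (≤ 0.1 % end-to-end), and
noisy runs bound their sampling error under the stated noise models.  They
do not establish performance on real tissue: the generator has no spatial
cortical-layer structure, B0 inhomogeneity, amyloid or myelin confounds, no
overlap of mineral phases in one IRM curve (each temperature sees a single
component), no EPR signals other than the g′ = 4.3 species, and
formalin-fixation chemistry is outside the model entirely.

## Pipeline

Six stages — simulate, r2star, epr, irm, assemble, stats — communicate only
through declared files (NIfTI, two-column CSV + JSON sidecar, cohort CSV),
so they can run as separate processes via the CLI verbs.  Per-subject
random streams are spawned from a single `SeedSequence`, every consumed
seed is logged, outputs carry no timestamps, and a rerun with the same
config is byte-identical.  The mass→molar conversion assumes a tissue
density of 1.0 g/mL and Fe at 55.845 g/mol (µM = µg/g · density/M_Fe ·
10³); physical constants are centralized in `ironforms.constants` with CGS
and SI views.

Default problem sizes (22 + 14 subjects, 24×24 voxel grids, 400 powder
orientations, 30-point IRM sweeps) keep a full run around a second on one
CPU while leaving all estimators in their asymptotic regimes; recovery
studies in the test suite scale the cohort up to 200 subjects.

## Known limitations

* The EPR forward model treats g-strain to first order in the resonance
  field and omits modulation broadening; strongly overlapping transitions
  with near-degenerate levels could make Hellmann–Feynman slopes unstable
  (guarded numerically, not observed with the default parameter set).
* R2\* retains the Rician low-SNR bias by design (documented above).
* The Langevin fit assumes a single particle-moment mode per temperature;
  multimodal moment distributions would bias μ_p toward the dominant mode.
* The Brown–Forsythe test and the outlier screen are slightly conservative
  at the published group sizes.
* Partial correlations use the first-order recursion on rank correlations;
  this is standard but not identical to a semiparametric copula treatment.
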