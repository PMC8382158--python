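# Methods

## Model

The package simulates three interacting tumour cell populations on a 1D
transect `x ∈ [0, L]`: EGFR-amplified (`E`), PDGFRA-amplified (`P`) and
non-amplified (`N`) concentrations in cells/mm³. Migration follows the
volume-filling ansatz: a population's diffusive flux is damped by the
space already occupied by the *other* populations and augmented by a
cross-diffusion term that pushes it down the gradient of total crowding,

    J_E = −D_E [ (1 − (P+N)/K) ∇E + (E/K)(∇P + ∇N) ],

with species permuted for `J_P`, `J_N`. Proliferation is jointly logistic
— growth stops when the total density `T = E + P + N` reaches the carrying
capacity `K` — with the amplified populations' net rates modified by each
other's density:

    f_E = ρ_E E (1 + α_PE P/K)(1 − T/K),
    f_P = ρ_P P (1 + α_EP E/K)(1 − T/K),
    f_N = ρ_N N (1 − T/K).

Two useful algebraic identities anchor the implementation and are enforced
by the test suite: (i) with equal diffusivities the three fluxes sum
exactly to the Fickian flux of `T`, and (ii) with equal rates and
`α_EP = α_PE = 0` the whole system collapses to a single Fisher–KPP
equation for `T` — the clinically calibrated Proliferation–Invasion model
of glioma growth. Both identities hold discretely, to round-off, under
the chosen discretization.

`K = 1/((4/3)π r³) = 2.39 × 10⁵ cells/mm³` for cells of radius `r = 10 µm`.
A strongly negative interaction (e.g. `α_EP = −5` with `E > K/5`) makes the
modified rate negative; this is interpreted as net death and fields are
floored at zero after each update.

### Mutation events

Tumours are initialized as a Gaussian bump of `N` cells,
`N(x,0) = (100/√π) e^{−(x−x*_N)²}`, whose line integral — the initial
tumour "size" `N_I` — is exactly 100 cells/mm². The amplitude convention
makes trigger sizes expressed as multiples of `N_I` exact; for internal
consistency the triggers use the trapezoidal value of `N_I` on the actual
mesh (100 to within 0.1%). The amplified populations are seeded by adding
the same bump (centred at `x*_E`, `x*_P`) to the corresponding field at
the end of the first time step where the trigger holds. Two trigger modes
exist, mutually exclusive per population: size-based (the line density of
`N` reaches `N_E` or `N_P` — the default, which makes mutation timing a
statement about *proliferation events* rather than clock time, so it
adapts to each tumour's growth rate) and time-based (`t*_E`, `t*_P`
directly, used by fixed-horizon demonstrations). End-of-step addition is a
choice; the delta-in-time source has no canonical placement within an
explicit step, and the smoothing effect of diffusion makes the difference
invisible at one step's resolution.

## Discretization

Uniform mesh (`L = 200 mm`, `dx = 0.25 mm`, 801 nodes), conservative
finite-volume-style fluxes at cell interfaces (central-difference
gradients, arithmetic averaging of coefficient fields onto interfaces) and
forward-Euler time stepping with `dt = 1/1500 years`. Zero-flux boundaries
are imposed by zeroing the boundary interface fluxes, which makes the
nodal sum of each field exactly conserved under pure transport (the suite
checks < 1e−8 relative drift over 1000 steps). Arithmetic inside the
update is grouped so that the scheme is bitwise symmetric under the E↔P
role swap and under spatial reflection; the baseline symmetric scenarios
therefore give *machine-zero* single-gene amplification proportions, not
merely small ones.

The stability guard rejects a step unless `2·max(D)·dt/dx² ≤ 1`, i.e. at
the exact forward-Euler diffusion bound. The default numerics give 0.64
for `D = 30 mm²/year` and 0.96 for the largest diffusivity reachable in
the studies (`1.5 × 30 = 45`); a stricter safety-factor guard would reject
parameter sets the studies themselves require, and the volume-filling
damping keeps the effective diffusivity below the nominal `D` wherever
crowding is non-negligible. Blow-up (non-finite values) raises
immediately. `max_time` defaults to 50 years — the slowest cohort member
(`ρ = D = 3`) reaches diagnosis size in ≈ 5.8 years, so hitting the cap
signals a genuinely non-growing parameter set and is reported as a stop
reason rather than raised.

## Clinical calibration and outputs

Simulations stop at the first step where the width of `T` above `0.8 K`
(node count × dx) reaches 36.2 mm, the mean volume-equivalent
T1Gd-MRI-derived diameter at diagnosis; the 0.8 K density level is the
standard mapping of enhancing-MRI margins onto the Proliferation–Invasion
model. A tumour is scored by node counting over the detectable region
`T > 0.1 K`: `A_E` is the fraction of detectable nodes with `E > 0.1 K`
and `P ≤ 0.1 K`, mirrored for `A_P`; `A_B` counts both above; `A_N` is the
remainder and therefore includes the sub-threshold tumour edge, which is
why `A_N` responds strongly to the parameters (`ρ_N`, `D_N`) that set the
edge profile's flatness. Ties at any threshold count as *not*
amplified/detectable (strict `>`); ties are measure-zero in floating
point, but the convention matches the calling rule for biopsies ("at or
below threshold is not called"). The detectable region need not be
contiguous.

The 10% detection fraction is the same convention as the CNA calling
threshold: a tissue sample that is a fraction `f` amplified cells (copy
number 4) in a diploid background (copy number 2) measures
`CNA = 2(1−f) + 4f`, so `f = 0.1` gives the 2.2 calling threshold, below
or at which a gene is not called.

## Scenario studies

A patient cohort's heterogeneity in proliferative and invasive potential
is emulated by running every scenario with four (ρ, D) pairs —
{3, 30}/year × {3, 30} mm²/year — and averaging the four proportion
vectors with equal weight (the cohort statistic is a mean of proportions,
matching how per-patient biopsy proportions are averaged). The sweep
families:

* **interaction**: symmetric `α ∈ {−5, 0, 5}` (competition, neutralism,
  cooperation), baseline otherwise;
* **advantage**: the four-config menu (a) E invasive ×1.5, (b) E invasive
  and proliferative ×1.5, (c) = (b) + P invasive ×1.5, (d) = (b) + P
  proliferative ×1.5, each crossed with the three α values;
* **timing**: P fixed at the trigger `6 N_I` while E's trigger runs over
  `(i+2) N_I`, `i = 1..7`; the `i = 4` cell is literally the same
  computation as the interaction sweep and reproduces it bitwise. The
  monotone trend (earlier E introduction → smaller `A_N`, larger `A_E`)
  applies to the early side `i ≤ 4`; on the late side `A_P` grows at the
  expense of both, so `A_N` is not monotone over the full range;
* **location**: introduction centres offset from the tumour centre by up
  to ±1.5 mm (the founding tumour spans only ~3 mm at introduction time);
  symmetric offsets produce exactly equal `A_E = A_P` by reflection
  symmetry of the scheme.

Triggers of `11 N_I` or later leave the amplified populations below
detectable levels at diagnosis size — the regression suite pins this, and
it motivates the `[3 N_I, 9 N_I]` trigger box of the sensitivity study.

## Sensitivity analysis

Latin hypercube sampling over 12 independent uniform parameters:
advantage multipliers `v^ρ_E, v^ρ_P, v^D_E, v^D_P ∈ [1, 1.5]`; triggers
`N_E, N_P ∈ [3, 9] N_I`; locations `x*_E, x*_P ∈ x_c ± 1.5 mm`; founding
rates `ρ_N ∈ [3, 30]/year`, `D_N ∈ [3, 30] mm²/year`; interactions
`α_PE, α_EP ∈ [−5, 5]` (sampled independently, so the asymmetric
interaction types are covered). Each design row is one simulation
(`ρ_E = v^ρ_E ρ_N` etc.); outputs are the four proportions. PRCC is
computed by the residual method — rank-transform all columns (average
ranks on ties), regress both the parameter's and the output's ranks on the
other 11 parameters' ranks, correlate the residuals — which is
algebraically equivalent to the precision-matrix formulation (the suite
checks agreement to 1e−10) and numerically stabler at this many
conditioning columns. Significance uses `t = r√(df/(1−r²))` with
`df = n − 2 − 11`, two-sided, starred at 0.05/0.01/0.001; the test's null
calibration is verified empirically (false-positive rate 5% ± 2% over 500
independent-data replicates). Failed simulations would be dropped
listwise with a logged count; none occur within the default box. The
reference design size is 2000; the shipped test suite and acceptance
script use n = 200, which is ample for the sign structure of effects with
|PRCC| ≳ 0.3 (null standard error ≈ 1/√n ≈ 0.07).

The location parameters act through distance-to-centre, a potentially
non-monotone (V-shaped) dependence that plain PRCC cannot see;
`split_nonmonotone` partitions the design at the domain midpoint and
recomputes PRCCs per half, reporting the other parameters alongside so
their consistency across halves can be checked.

## Synthetic biopsy cohorts

No patient-level data ship with the package; the generator produces a
structurally matched stand-in: 25 patients, biopsy count uniform on
[2, 14], per-biopsy latent category drawn from weights defaulting to
(0.17, 0.54, 0.06, 0.23) for (neither, only-EGFR, only-PDGFRA, both) —
the cohort-level frequencies reported for image-localized GBM biopsy
studies — with CNA values emitted by the two-copy/four-copy mixture at an
amplified fraction uniform on [0.2, 0.8] per amplified gene, plus additive
Gaussian measurement noise (default sd 0.05, a knob: no published aCGH
noise model constrains it). The generator emulates the *structure* of
such cohorts, not their spatial sampling or per-patient correlation:
biopsies are exchangeable within a patient, there is no within-tumour
spatial autocorrelation, no "highly amplified" (>100 copies) minority
cells by default (available via per-record copy-number overrides), and no
failed-assay samples. Passing recovery tests therefore demonstrates the
calling/summarizing pipeline, not realism of aCGH noise.

Virtual biopsies bridge simulation and assay: a probe window (default
half-width 0.5 mm — tissue lumps are large compared with the 0.25 mm
mesh) averages each field, the averaged fractions of `K` feed the same
copy-number mixture, and classification proceeds as for real samples. A
dense transect of virtual biopsies, restricted to windows whose mean `T`
clears the detection threshold, reproduces the node-counting proportions
up to window smoothing at region boundaries (a few windows per boundary,
bounded in the tests by `8(h + Δ)/W` with probe half-width `h`, spacing
`Δ` and detectable width `W`).

## Numerical choices and limitations

* Arithmetic-average interface coefficients: second-order and preserve
  the sum-to-Fick cancellation exactly.
* Trigger checks run every step against the trapezoidal line density;
  an event fires at the end of the first step meeting its condition, so
  realized introduction times are quantized to `dt`.
* Width stopping overshoots the 36.2 mm target by at most the width
  growth of one step (the discrete width itself is quantized to `dx`,
  e.g. 145 nodes × 0.25 mm = 36.25 mm).
* Determinism: the solver contains no randomness; identical inputs give
  bitwise identical tables. Seeds enter only through the LHS design and
  the synthetic cohorts.
* 1D only. Curvature effects, anisotropic/tissue-dependent diffusion,
  resource dynamics and stochastic single-cell mutation events are out of
  scope; the front-speed and reduction checks validate the numerics, not
  3D realism.
* Test-suite problem sizes are scaled (single-pair cohorts for machinery
  tests, n = 200 sensitivity designs, 500-replicate calibrations) —
  chosen as the smallest sizes at which the checked properties are
  clearly resolved.
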