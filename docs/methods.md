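# Methods

## Scope and model chain

The package covers the desk-scale half of a multiscale BNCT effectiveness
calculation: everything downstream of neutron/photon transport. Users
supply per-component absorbed doses (or dose fractions) of a mixed field,
each tagged with its biophysical inputs — the relative DSB yield RBE_DSB
and the frequency-mean specific energy z̄F. The package computes z̄F itself
for ion components (analytically or by chord Monte Carlo), maps
(RBE_DSB, z̄F, α_γ, β_γ) to test-radiation LQ parameters through the RMF
asymptotic limits, aggregates mixed fields by dose weighting, and layers
BNCT-specific bookkeeping (capture source terms, subcellular boron
microdistribution, CBE) on top. Neutron transport, beam models and DSB
damage-induction simulation are out of scope by design; their outputs are
this package's inputs.

## Microdosimetry

*Analytic formula.* z̄F = k·LET/(ρd²) with k computed from first
principles: mean energy per µ-random crossing = LET·(2d/3) keV, sphere mass
= ρ·πd³/6 (in g·µm³ units), keV→J = 1.602176634·10⁻¹⁶. This gives
k = (4/π)·0.1602… = 0.20400 (3 d.p. 0.204). The formula assumes constant
LET along a full crossing; it overestimates z̄F when the CSDA range is
comparable to the target diameter.

*Chord Monte Carlo.* µ-randomness is sampled exactly: impact parameter
squared uniform on [0, R²], chord ℓ = d√(1−b²/R²) (density 2ℓ/d², mean
2d/3). Internal emitters are sampled uniformly in the source volume with
isotropic directions. Tracks are straight CSDA trajectories; energy
imparted over a path [s_in, s_out] is evaluated by inverting the
range–energy relation, ΔE = E(R₀−s_in) − E(R₀−s_out), which is the *exact*
integral of LET ds and therefore needs no step-size parameter — the only
discretization is the stopping-power grid itself (400 log-spaced points by
default). Residual ranges below the table floor use a constant-LET closure
(a sub-permille effect for a 1 keV-scale floor). Delta-ray escape, lateral
track structure and energy-loss straggling are neglected; for the
micrometre targets and MeV ions of interest these shift z̄F by far less
than the biological uncertainties in RBE_DSB, but they are real
approximations of this simulator, not of the underlying data.

*Stopping tables.* Interpolation is log-log linear and extrapolation is an
error. The bundled tables in `stopping.py` are synthetic: a one-anchor
power-law range model R = aE^b per ion, calibrated so LET and CSDA range
are exact at one characteristic energy per capture product (0.59 MeV p,
1.47 MeV α, 0.84 MeV ⁷Li). The identity LET·R = E/b fixes b. At the
anchors' sibling energies the synthetic LET is within ~2–10% of evaluated
data — adequate for ordering/limit studies and tests; substitute ICRU/SRIM
tables (same CSV format, `energy_MeV,let_keV_um`) for quantitative work.

*Track metrics.* Relative DSB per track = z̄F·RBE_DSB; absolute DSB per
track additionally multiplies Σ_γ (DSB Gy⁻¹ Gbp⁻¹; representative photon
value ≈ 8.7) and the nuclear DNA content (≈ 6 Gbp mammalian diploid). The
µm-per-DSB spacing divides a path length by that count; the mean chord is
the default path, but for stoppers the CSDA range is the physically
meaningful choice and is accepted via `path_length` (using the chord there
inflates the spacing artificially).

*(Z_eff/β)².* Relativistic β from kinetic energy and A·931.494 MeV rest
mass; Barkas form Z_eff = Z·[1 − exp(−125·β·Z^(−2/3))]. This reproduces the
standard high-LET similarity scale (the alpha-particle DSB-per-track peak
sits near (Z_eff/β)² ≈ 4500).

## RMF mapping

The asymptotic limits assume intra-track binary misrepair is negligible for
the low-LET reference (the derivation's ≤1% condition); no correction term
is added. α_p and β_p follow algebraically; the quadratic for the
photon-isoeffective dose is solved with the cancellation-free root form
2c/(α_γ + √(α_γ² + 4β_γc)). Dose averaging of both RBE_DSB and z̄F uses
plain absorbed-dose weights — the literal mixed-field rule — and is
associative over any partition of the field, which the tests exercise. A
reference-radiation correction (e.g. 1.1 when the experimental reference
was 250 kVp X-rays rather than ⁶⁰Co) is a multiplicative scalar applied to
reported RBEs and stored in every result object; the default is 1.0 and it
is never applied implicitly.

## BNCT source terms

Branch energies are fixed kinematic constants: (α 1.47, ⁷Li 0.84,
γ 0.478) MeV for the excited branch and (α 1.78, ⁷Li 1.01) MeV for the
ground branch, satisfying the 7:4 two-body momentum partition. The
excited-branch fraction defaults to the standard nuclear-data value 0.937
and is configurable. The ¹⁴C recoil energy from ¹⁴N(n,p) is the
momentum-balance value E_p/14; by default it belongs to the `heavy_ion`
component. The 0.478 MeV de-excitation photon carries RBE 1 in the photon
component and is not micro-transported (mean free path ≫ cell).

## Cell dosimetry

Concentric spheres: nucleus (default radius 2.5 µm, matching the 5 µm
microdosimetry target), cytoplasm (default 5 µm), and an extracellular
shell whose default thickness (12 µm) exceeds the longest product range
(~10 µm for the 1.78 MeV alpha) so distant sources are not artificially
truncated. Capture sites are drawn with probability ∝ compartment
volume × ppm, uniformly within the compartment; each capture emits its α
and ⁷Li back-to-back isotropically and both tracks are scored against the
nucleus by the same range–energy inversion as the event simulator. Energy
conservation holds per event by construction (deposit in nucleus + deposit
elsewhere = branch kinetic energy, since straight CSDA tracks stop within
the medium).

Carrier presets: `bpa-in-vivo` (40 ppm cytoplasm, 0.4 ppm nucleus — the
~100:1 partition of boronophenylalanine observed in vivo), `bpa-in-vitro`
(27 ppm homogeneous over nucleus+cytoplasm), `mab` (100 ppm cytoplasm only,
the conservative no-nuclear-localization reading of an antibody carrier)
and `mab-membrane` (100 ppm just outside the cell) — the two mAb presets
bracket the unresolved question of where an antibody-bound compound
actually sits. The microdistribution weight is the ratio of mean nucleus
energy per emission between two scenarios at identical emission counts and
geometry; it rescales the boron dose component when moving between carrier
scenarios. Being a per-emission ratio it is invariant to the ppm level of a
fixed-shape distribution (ppm changes the capture *rate*, which is already
in the boron absorbed dose).

## Survival analysis

LQ fits run in log space, where the model is linear: weighted least squares
of −ln S on (D, D²) with weights 1/SE(ln S)² (SE(ln S) ≈ SE(S)/S) when
standard errors are given, else unweighted. Non-negativity of (α, β) is
honored by bounded optimization only when the unconstrained optimum is
infeasible, so interior solutions are exact to linear-algebra precision.
The one-parameter RMF fit holds β_p at the high-dose limit and fits only
z̄F, which is again linear in log space and solved in closed form with a
clip at the z̄F ≥ 0 boundary. The synthetic generator uses multiplicative
lognormal noise on S (the usual colony-count error model), truncated at 1;
its defaults in the recovery studies are 8 dose points, 3 replicates and
σ = 5%, a typical clonogenic-assay design. Because the published survival
datasets behind the original model benchmarks are not reproducible from
printed values alone, the validation surface here is parameter recovery on
synthetic data plus the printed-table consistency checks.

## Numerical and testing choices

- RNG: one `numpy` Generator per simulation call, seeded explicitly; seeds
  are recorded in result objects, and fixed seeds give bit-identical
  results.
- Problem sizes: 10⁶ events for the constant-LET convergence check (MC
  error ~n^(−1/2); <1% at that n), 5×10⁴ emissions per cell-dosimetry
  scenario, 500 seeds for the noisy-recovery medians. These complete in
  seconds on one core.
- The chord sampler, the uniform-compartment sampler and the lognormal
  noise model are tested against closed forms (KS tests, binomial and CLT
  bands at 3–4σ).
- Degenerate inputs fail loudly: zero total dose, empty fields, all-zero
  boron, out-of-domain table energies and zero-DSB tracks raise; an event
  spectrum in which nothing hit the target is flagged (`all_missed`) rather
  than reported as z̄F = 0.

## Known limitations

- The synthetic stopping tables are calibrated at one energy per ion; LET
  away from the anchor deviates by up to ~10% and the power law cannot
  represent a Bragg-peak maximum. The transport code is agnostic to where
  the table comes from.
- Straight-track CSDA transport ignores straggling and delta-ray transport;
  the in-house event simulator therefore approximates, but does not equal,
  a full damage-induction code's stopper-corrected z̄F column.
- RBE_DSB values are inputs, not computed; the RMF's known tendency to
  overestimate killing above ~100–200 keV/µm (all DSBs weighted equally
  regardless of proximity) is inherited by anything built on those inputs.
- The LQ/RMF surface treats survival as exponential in (D, D²); no
  lesion-kinetics ODE integration, dose-rate effects or bystander/tissue
  effects are modeled.
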