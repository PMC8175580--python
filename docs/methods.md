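# Methods

## Model

`minslab` implements the skeleton MinDE reaction–diffusion model in a slab
bounded by one or two membranes. Three bulk species diffuse in the cytosolic
volume — MinD-ADP (`c_DD`), MinD-ATP (`c_DT`), and MinE (`c_E`), all in
μm⁻³ — and two membrane species live on each membrane face: MinD (`m_d`) and
the MinDE complex (`m_de`), in μm⁻². The only bulk reaction is nucleotide
exchange, `c_DD → c_DT`, at rate λ. All membrane kinetics enter as reactive
boundary conditions:

    attachment:   (k_D + k_dD·m_d)·c_DT|_b     (removes MinD-ATP from the bulk)
    recruitment:  k_dE·m_d·c_E|_b              (removes MinE from the bulk)
    detachment:   k_de·m_de                    (releases one MinD-ADP and one
                                                MinE back into the bulk)

    ∂t m_d  = D_m ∂x² m_d  + attachment − recruitment
    ∂t m_de = D_m ∂x² m_de + recruitment − detachment

Total MinD (`c_DD + c_DT + m_d + m_de`) and total MinE (`c_E + m_de`) are
conserved; all pattern formation is redistribution of these two pools.
Assumptions inherited from the skeleton form: no membrane saturation, no
MinE conformational switching (the model does not form patterns for
E:D ≳ 1), ATP/ADP enter only through the DD/DT split, and mass-action
kinetics throughout.

Key derived scale: the penetration depth ℓ = sqrt(D_b/λ) over which
cytosolic MinD-ADP gradients decay away from a membrane. The critical
height H_c of the membrane-to-membrane oscillation is set by ℓ and the
kinetic rates.

## Parameters

The shipped parameter file `data/skeleton_fallback.yaml` is a **calibrated
fallback set, not a transcription of measured rates**. It was fixed, before
any acceptance checks were written, by a randomized search over rate space
scored on the qualitative phase-diagram topology, followed by an exact
space–time rescaling (x → s·x, t → s²·t, which leaves both diffusivities
invariant and rescales every H_c by s) to place the critical height near
5 μm:

| parameter | value | units | meaning |
|---|---|---|---|
| k_D | 0.0215 | μm s⁻¹ | spontaneous MinD-ATP attachment |
| k_dD | 0.2924 | μm³ s⁻¹ | cooperative MinD recruitment |
| k_dE | 0.3939 | μm³ s⁻¹ | MinE recruitment onto membrane MinD |
| k_de | 0.3122 | s⁻¹ | MinDE hydrolysis / detachment |
| λ | 1.5929 | s⁻¹ | cytosolic nucleotide exchange |
| D_b | 60 | μm² s⁻¹ | bulk diffusivity (all bulk species) |
| D_m | 0.013 | μm² s⁻¹ | membrane diffusivity |
| n_D | 231.1 | μm⁻³ | mean total MinD (≈ 0.38 μM) |
| n_E | 173.3 | μm⁻³ | mean total MinE (E:D = 0.75) |

With this set: the m-to-m mode first becomes unstable at H_c ≈ 4.3–5.3 μm
depending on E:D (minimum ≈ 4.3 at E:D ≈ 0.79); at E:D = 0.75 only the
lateral mode is unstable below H ≈ 4.8 μm; and at large heights the two
membranes decouple. Oscillation periods are ~10–20 s and lateral
wavelengths ~20–30 μm — within an order of magnitude of, but not fitted
to, measured Min scales (wavelength/period matching is a known open problem
for this model class; only qualitative regime structure is meaningful).
The parameter schema supports per-species bulk diffusivities (`D_b_D`,
`D_b_E`) and converts μM inputs at the I/O boundary (1 μM = 602 μm⁻³).

## Homogeneous steady state

At stationarity `c_E` and the summed field `c_DD + c_DT` are uniform in z
(each obeys pure diffusion with zero net boundary flux), while `c_DD` is a
cosh profile with decay length ℓ centred on the slab midplane (both-faces)
or the far wall (bottom-only). The mass constraints and the
recruitment–detachment balance reduce the problem to one scalar equation in
`m_de`, bracketed on a scan and solved with Brent's method; the returned
residual is the relative violation of the three flux balances (typically
~1e-16). With no attachment pathway (k_D = k_dD = 0) the empty-membrane
state is returned directly.

## Linear stability analysis

Perturbations ∝ exp(σt + iqx) separate by the slab's mirror symmetry into
symmetric (in-phase membranes) and antisymmetric (antiphase) sectors. In
the bulk-reaction eigenbasis u = c_DD (rate λ), w = c_DD + c_DT (rate 0),
e = c_E (rate 0) each component has an analytic vertical profile with decay
rate α = sqrt(q² + (σ + r)/D); eliminating the bulk gives a 5×5 boundary
matrix in (u₀, w₀, e₀, δm_d, δm_de) whose determinant roots are the growth
rates. Numerics:

* the determinant is row-normalized so magnitudes are comparable across σ;
* roots are found by a rectangular scan of the upper half plane
  (Re σ ∈ [−5, 5], Im σ ∈ [0, 5] s⁻¹, conjugates implied) followed by
  Newton polishing with a central-difference derivative; purely real seeds
  are nudged off the real axis (a real iteration can never reach a
  conjugate pair);
* at q = 0 in the symmetric sector, conservation of the two totals forces
  an exact double root at σ = 0; it is deflated analytically (σ² divided
  out) so it can never leak into the membrane-to-bulk classification.
  A |σ| < 1e-6 window is kept as a safety net — looser than first
  planned (1e-8) because a numerically polished double root is only
  accurate to about sqrt(machine ε);
* branches are continued in q from their previous values, with step-halving
  on jumps and root deflation when two branches collide (the neutral double
  root splits into two mass-redistribution branches at q > 0, which carry
  the lateral instability); lost branches are reported as NaN.

Classification: lateral ⇔ max Re σ > 0 at q > 0 on either parity;
membrane-to-membrane ⇔ antisymmetric q = 0 root with Re σ > 0;
membrane-to-bulk ⇔ symmetric q = 0 root with Re σ > 0 after neutral-root
exclusion. `critical_height` locates the m-to-m onset by a coarse H scan
(which also catches re-entrant stability windows) plus bisection to 0.05 μm.
The closed-form propagator was validated against a dense finite-difference
boundary-value solve, and full determinant roots against a brute-force
eigendecomposition of the discretized vertical problem (both kept as test
oracles).

## Nonlinear slice simulations

Cell-centred finite volumes on a uniform (x, z) grid, reflective side
walls. Each step is a Strang split: half-step lateral diffusion (θ-scheme,
batched tridiagonal solves), a full vertical step, half-step lateral
diffusion. The vertical step advances z-diffusion, nucleotide exchange, and
the membrane exchange *in one implicit solve per column*: with membrane
densities frozen over the step the attachment/recruitment drains are linear
in the boundary concentration, so each bulk species reduces to a
tridiagonal θ-solve with drain/source terms on the boundary cells; the
MinD pair is advanced in the (u, w) reaction eigenbasis so λ contributes no
splitting error. The mass each column loses or gains is transferred to the
membrane fields by exact column-sum bookkeeping, making conservation
independent of step size (observed drift ~1e-12 relative, round-off).

Two properties were decisive in validation:

* the scheme's fixed point is independent of dt and θ (frozen coefficients
  are exact at stationarity), so a stable steady state persists to the
  O(dz²) sampling error of the initial condition (< 1e-4 relative at
  dz ≈ H/48);
* seeded small-amplitude runs grow at the LSA rate within 1–2% at
  dt = 0.01–0.02 s, comfortably inside the 5% cross-validation band.

Boundary rates are evaluated at flux-consistent half-cell extrapolated
concentrations, removing the O(dz) error of using cell-centre values.
Positivity is enforced by step rejection with halving (never clipping);
defaults: dt = 0.01–0.02 s, θ_z = 0.55 (mild damping of vertical ringing),
θ_x = 0.5, dz ≈ 0.1–0.5 μm, dx = 0.5 μm.

Problem sizes: production-scale Min chambers are hundreds of μm wide; this
package's standard analyses use reduced slices of 4–5 dominant wavelengths
(L_x ≈ 60–100 μm, grids of order 200×(16–100) cells, runs of 300–500 s),
which is sufficient for regime classification and synchronization
statistics while keeping a full pipeline run on a laptop-class CPU in
minutes. Larger domains are config-reachable.

Growth-rate measurement (`measure_growth_rate`) projects the membrane
density on the cos(qx) wall eigenmode, estimates the envelope rate from the
analytic signal, and refines (rate, frequency) by nonlinear least squares
on A·exp(σ_r t)·cos(ωt + φ).

### Adiabatic height sweeps

The sweep treats the slab as a closed system: stepping H moves the ceiling
but neither adds nor removes protein. Bulk profiles are re-gridded by
interpolation in depth-from-the-nearest-membrane (boundary layers
preserved, midplane extended/truncated) and rescaled so each species' bulk
mass is *exactly* unchanged; membranes carry over untouched. The E:D ratio
is invariant along the sweep while volume-averaged concentrations scale as
1/H, so the sweep path crosses the m-to-m onset along a hyperbola of
constant protein number rather than a vertical line of constant
concentration — the physically consistent reading of a continuously
deformed chamber, and unconditionally free of the negative-concentration
pathologies a fixed-concentration rescale produces when the membranes hold
more protein than a shrinking target total. Each segment is classified from
its kymograph; hysteresis is read off as differing transition heights
between up and down sweeps.

## Pattern classification

The paper-level pattern classes are identified from the space-time spectrum
of a kymograph (movies are first reduced to a kymograph along the dominant
pattern orientation):

1. no clear temporal spectral line (contrast < 4 over the median) or fewer
   than 3 oscillation cycles → `indeterminate`;
2. dominant spatial wavenumber at the oscillation line below 4 grid bins
   (and not captured by the standing branch below) →
   `homogeneous_oscillation`. This deliberately includes phase waves:
   apparent motion with a snapshot wavelength comparable to the domain
   carries no lateral mass transport and is phenomenologically a patchwise
   in-phase oscillation;
3. otherwise the domain is split into 8 windows and the power asymmetry
   between the two propagation diagonals of (k, ω) is computed per window;
   median |asymmetry| ≤ 0.5 with at least 2 spatial-frequency bins of
   structure → `standing_wave` (locally balanced counter-propagating
   power); > 0.5 with at least 4 bins → `traveling_wave` (also with
   counter-propagating trains in different windows).

A demodulation-based metric set (circular phase spread, doubled-phase
spread, |∇φ| statistics) is attached to every label for inspection. An
earlier decision rule based directly on those phase metrics misclassified
the model's own reference states (phase waves span several 2π; wave trains
separated by defects break gradient uniformity), which motivated the
spectral rule; all thresholds are config-exposed
(`ClassifierThresholds`) and were frozen against the generator fixtures and
the three reference simulations.

## Image correction and scales

`correct_stack` follows the standard three-step pipeline with two
robustness choices worth noting:

* the bleach trend divides out an *exponential fit* to the frame means
  rather than each raw mean — in a field of view only a few wavelengths
  across, the frame mean oscillates with the pattern phase, and raw
  per-frame normalization imprints a spurious global oscillation;
* the static background (specks, scratches) is the 20%-trimmed temporal
  mean minus its small-scale-blur baseline. A plain temporal median has an
  O(amplitude) bias when a periodic signal is sampled at few phases per
  period (30–60 s frames vs ~2 min periods); the trimmed mean keeps the
  outlier robustness without that bias.

The illumination field is the strongly blurred (default σ = ¼ image side),
static-subtracted frame average normalized to max 1; pixels below a
configurable floor raise an error. The correction is
`(frame − static)/illumination`; on the full default artifact stack the
recovered wave is within ~4% RMSE of the clean reference.

The dominant wavelength samples each frame's unbiased (zero-padded)
autocorrelation along the dominant spectral orientation and takes the first
side maximum (median over 10 frames); an isotropic radial average was
rejected because a plane wave's radially averaged autocorrelation is a
Bessel profile whose first side lobe sits at 1.12 wavelengths. The dominant
period is the first side maximum of the temporal autocorrelation, median
over 20 kymographs (10 per axis) drawn from the central 70% of the image,
with the median taken pointwise across curves. Both estimators return None
(with the floor used) when no side maximum clears the noise floor.

Dual-plane synchronization divides the field of view into whole ≈10×10 μm²
cells (partial edge cells dropped), Pearson-correlates mean-subtracted
cell-average traces over the window (default 100 s for simulations, full
movie otherwise), and classifies with strict thresholds: correlated
> +0.7, anticorrelated < −0.3, boundary values count as neither.
Constant-trace cells are excluded and counted.

## Synthetic data

The generator renders the four wave classes (traveling, standing,
homogeneous, phase-wave) as pure sinusoidal fields with calibrated pixel
size and frame interval, then applies artifacts in a fixed order:
exponential bleach (default 20% total decay) × Gaussian vignette, plus a
static speck image, then Gaussian (default σ = 1 intensity unit ≈ 2.5% of
the wave amplitude, a high-signal spinning-disk regime) or Poisson noise.
Dual-plane pairs phase-shift the bottom plane and optionally replace a
random fraction of 10 μm cells with independently seeded waves at an
incommensurate frequency so their traces genuinely decorrelate. Everything
is a pure function of spec + seed.

What the generator does *not* emulate: point-spread blur, camera gain maps,
registration offsets between planes, pattern curvature/defects, or
intensity nonlinearity. Passing the recovery matrix therefore demonstrates
correctness of the analysis pipeline's estimators under controlled
distortions, not performance on raw microscope output.

## Known limitations

* The fallback parameter set reproduces the regime topology and the ~5 μm
  critical height, but absolute wavelengths/periods are faster and shorter
  than experimental Min patterns; only class-level comparisons are
  meaningful.
* The 2+3D box geometry is supported in structure (the slice code
  generalizes) but not exercised; all shipped analyses are 1+2D slices at
  reduced lateral scale, plus laterally uniform 1D-in-z columns.
* The LSA assumes the two-membrane slab's mirror symmetry (both-faces
  geometry); bottom-only slabs are simulated but not classified by parity.
* Standing-wave *chaos* appears in large domains; at the reduced scales
  used in tests the standing states are only weakly disordered.
* For E:D ≳ 0.85 the homogeneous steady state loses the membrane-bound
  branch and the model forms no patterns, consistent with the skeleton
  model's known E:D < 1 validity range.
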