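# Methods

`oligokin` analyses the biophysics of sub-stoichiometric chaperone
inhibition of amyloid formation: seeded aggregation kinetics monitored
by ThT fluorescence, detection of transient oligomers through the size
increase of a fluorescent chaperone probe in microfluidic diffusional
sizing (MDS), equilibrium chaperone–oligomer binding, oligomer
dissociation kinetics, and small-angle X-ray scattering of the
fibril/monomer mixture.  This note records the models, their
assumptions, the defaults, and the numerical choices.

## Aggregation kinetics (`oligokin.kinetics`)

Fibrils are described by two moments: number concentration `P` (fibril
particles) and mass concentration `M` (monomer equivalents), with free
monomer `m = m_total − M`:

    dP/dt = k_n m^n_c + k_2 m^n_2 M
    dM/dt = 2 k_plus P (m − m_eq)

Primary nucleation (`k_n`, order `n_c`), secondary nucleation catalysed
on the fibril surface (`k_2`, order `n_2`), and elongation at both
fibril ends (`k_plus`).  This two-moment closure is the minimal system
that supports the three competing chaperone-action hypotheses (see
below); fragmentation and length-resolved distributions are out of
scope.

**Solubility-limited elongation.** The net elongation rate is
proportional to the supersaturation `m − m_eq` rather than to `m`.
This matters for this peptide: the fibril solubility (3.5 mM) is a
large fraction of the 5 mM total, so the fluorescence plateau coexists
with millimolar free monomer and a pure-`m` driving force would be
qualitatively wrong.  The nucleation terms keep `m` itself — a
deliberate simplification; at these concentrations the distinction only
rescales `k_n`/`k_2` and does not change the hypothesis ranking.

**Seeds.** `M(0) = seed_mass × active_seed_fraction`,
`P(0) = M(0)/L0`.  `L0 = 500` monomers per seed is the assumed mean
size of bath-sonicated seed fibrils; the experiments report seed mass
only, so `L0` is a config parameter.  Because seed number enters the
kinetics logarithmically (secondary nucleation amplifies whatever is
present), results are insensitive to factor-of-two changes in `L0`.

**Defaults** (units: mM, hours): `k_plus = 50 mM⁻¹h⁻¹`,
`k_2 = 9.928e-5 mM⁻²h⁻¹`, `k_n = 0`, `n_c = n_2 = 2`,
`m_total = 5 mM`, `m_eq = 3.5 mM`, seeds 0.7% (0.035 mM).  The two
rate constants were solved (once) so that the seeded half-time is
6.5 h, the centre of the observed 6–7 h window; with seeds present and
secondary nucleation active, primary nucleation is negligible and is
disabled by default.

**Oligomer channel.** `dO/dt = k_2 (m − m_eq)₊^{n_2} M − k_loss O`.
Oligomers are generated by the same surface-catalysed process that
dominates oligomer production in seeded systems, but from
*supersaturated* monomer only: the `(m − m_eq)₊` factor makes the
source vanish at equilibrium, so the population rises during growth and
decays back to zero at the plateau — without it, `O(∞)` would be a
finite constant, contradicting the observed return of the probe signal
to its free-monomer baseline.  `k_loss = 3.5 h⁻¹` by default, the
measured 37 °C oligomer dissociation rate.  The absolute scale of `O`
is not constrained by data; only its shape is used.

**Hypothesis fitting.** Traces are normalized by an affine
baseline/plateau rescale (first 5 points / last 10% of points; ThT
assumed linear in fibril mass), with the identical estimator applied to
model curves so the comparison carries no normalization bias.  Fits use
the median of replicates per chaperone concentration.  The 0 nM group
anchors shared `(k_plus, k_2)`; each chaperone concentration then frees
exactly one parameter according to the hypothesis — `k_plus` reduction,
`k_2` reduction, or seed inactivation (`active_seed_fraction`, fitted
through a logistic transform to stay in (0, 1]).  The total error
square sum ranks the hypotheses.  Seed inactivation shifts the lag
while preserving the trace shape; rate reductions flatten the growth
phase — this shape difference is what the ranking detects.

**Numerics.** LSODA (stiff-capable, adaptive) at `rtol 1e-8`,
`atol 1e-10`; mass conservation holds to 1e-6 relative at all output
times and the solution agrees with a fixed-step RK4 reference at 10×
finer step to 1e-4.

## Diffusional sizing (`oligokin.mds`)

The instrument co-flows labelled sample and buffer; the measured
"diffused fraction" f (fluorescence in the chamber opposite the inlet
over total) increases with diffusivity from 0 to ½.  The instrument's
proprietary inversion is not public, so the channel is modelled as 1-D
diffusion of a step profile across two unit-width half-channels with
reflecting walls; with diffusion number τ = κD,

    f(τ) = 1/2 − (4/π²) Σ_{k odd} k⁻² exp(−k²π²τ/4).

The effective channel constant κ (s·m⁻², one per instrument size
range) absorbs transit time and geometry and is calibrated from a
single anchor: the free chaperone monomer, R_h ≈ 3 nm at f ≈ 0.42,
giving κ = 8.04×10⁹ s·m⁻² for the default range.  Ranges 2 and 4 ship
with κ/2 and 2κ, spanning the instrument's 2–17 nm sensitivity band.
Absolute κ values are not comparable to the vendor's; all downstream
analysis needs only the anchored, strictly monotone fraction↔radius
map.  Radii convert to diffusivities via Stokes–Einstein
(`D = k_B T / 6πηR_h`; defaults 298.15 K, 0.89 mPa·s).

Mixtures mix linearly in *fraction* space weighted by label fraction —
the instrument records one intensity split per sample — and the
apparent ⟨R_h⟩ is the inversion of that mixed fraction.  This convention
under-weights large species (a 50/50 mixture of 3 and 11 nm species
appears below 7 nm), which is exactly the averaging bias the titration
experiments are designed around.  Fractions marginally above 0.5
(noise) are clipped to 0.4999 with a QC warning.  The labelling degree
of the probe does not enter: only labelled molecules are observed.

Numerics: the series is summed to 51 odd terms (converged to < 1e-10
over the physical 0.5–50 nm range); inversion is by bisection to
1e-4 nm on the default R ∈ [0.5, 50] nm window, raising an
out-of-range error otherwise (the instrument's "size determination not
possible" condition).  The forward map agrees with a Crank–Nicolson
finite-difference solution of the same initial/boundary problem to
1e-4 absolute.

## Binding isotherm (`oligokin.binding`)

Total probe `C_JB6` (12.5 nM) mixed with supernatant volume fraction X
containing sites `S = X·C_s`.  Independent one-to-one binding with
depletion gives the quadratic root

    B = [(C+S+K_D) − sqrt((C+S+K_D)² − 4CS)]/2,
    f(X) = f_0 + (f_b − f_0)·B/C_JB6,

evaluated in the cancellation-free form `2CS/(b + sqrt(b²−4CS))`.  The
fit is performed on raw diffused fractions (not radii), jointly over
replicates, by trust-region least squares in `(log10 K_D, log10 C_s,
f_0, f_b)` with multistart over K_D ∈ {0.1, 1, 10, 100} nM and two
C_s starts (from the empirical transition midpoint and from
`C_JB6/X_max`) — the flat low-K_D likelihood makes single starts
fragile.  Bootstrap standard errors resample replicates within each X.

Because `C_JB6 ≫ K_D` here, binding is depletion-dominated and K_D is
identified only from above: the e.s.s. profile (re-optimizing C_s,
f_0, f_b at fixed K_D) is flat below ~1 nM and rises above ~100 nM.
The profile routine reports the K_D interval within a configurable
e.s.s. ratio (default 1.25).  `C_s` is an upper limit to the oligomer
concentration (one probe site per oligomer); this caveat is attached to
every fit result.

## Dissociation kinetics (`oligokin.dissociation`)

Apparent size versus incubation time is fitted with
`⟨R_h⟩(t) = a·exp(−k_off·t) + c` (bounds a, k_off ≥ 0,
0 < c ≤ ⟨R_h⟩(0)), replicate-level points when available, otherwise
1/sd² weights on means.  A series whose fitted amplitude is
indistinguishable from zero (a ≤ max(3·RMSE, 0.01 nm)) is flagged
unidentifiable and refused in comparisons.  Rate ratios carry a
percentile CI from a within-timepoint replicate-resampling bootstrap
(default 2000 resamples, seeded).  No correction is applied for the
dilution of probe-incubated samples at time zero (which raises their
net dissociation rate slightly); the caveat is attached to every
comparison result.

## SAXS (`oligokin.saxs`)

`I(q) = A q^{−p} + c_scale·c·P_Debye(q, R_g) + bkg` with the Debye
random-coil form factor `P = 2(e^{−u} − 1 + u)/u²`, `u = (qR_g)²`
(series branch below u = 1e-4, where the closed form loses precision to
cancellation).  The low-q power law is an empirical description of the
heterogeneous, attractively interacting fibril network (exponent ≈2.3,
far from the q⁻¹ of dilute rods); the coil term assumes S(q) ≈ 1
despite the millimolar concentration, since inter-monomer structure is
absorbed into the empirically fitted low-q regime.  The absolute
contrast constant (`c_scale`, intensity per mM at q→0) is treated as a
known calibration input; computing it from electron densities is out of
scope, and the synthetic generator uses the same constant, which makes
concentration recovery well-posed.

The staged fit does (i) log–log regression on q < 0.03 Å⁻¹ for (A, p),
(ii) weighted least squares on q > 0.06 Å⁻¹ (the monomer-dominance
threshold) for (R_g, c, bkg) with the power law fixed, (iii) joint
weighted refinement of all five parameters (default on), with
Gauss–Newton standard errors.

## Synthetic scenarios (`oligokin.synthetic`)

Each scenario is a pure function of (scenario id, seed, noise,
overrides) — identical seeds give identical bytes.  Defaults encode the
study conditions:

| scenario | emulates | key defaults |
|---|---|---|
| `fig3a` | seeded ThT traces, 0–1000 nM chaperone | t½ = 6.5 h at 0 nM; seed inactivation `1/(1+[JB6]/K_inact)`, K_inact = 0.936 nM so 50 nM doubles t½; N = 7/5 replicates; ThT = 100 + 600·M a.u., σ = 10 |
| `fig4a`/`fig4b` | probe ⟨R_h⟩ versus withdrawal time | co-oligomer 11 nm (5 nm for the fast-peptide analogue), free probe 3 nm, sites ∝ O(t) peaking at 2000 nM, K_D = 1 nM, C = 12.5 nM; 7–15 replicates |
| `fig4c` | probe titration 3–75 nM at X = 2.5% | K_D = 1, C_s = 400 nM; σ_Rh = 0.5 nm; 4–6 replicates |
| `fig4d` | supernatant titration, X ∈ [1.4e-4, 0.75] | f_0 = 0.42, f_b = f(11 nm) = 0.2388, C_s = 400 nM, K_D = 1 nM; 4–6 replicates |
| `fig5_37C`/`fig5_23C` | dissociation decays ± probe | 7·e^(−k_off t) + 3 nm; k_off = 3.5/1.9 (37 °C), 1.3/0.8 h⁻¹ (23 °C); 13 timepoints over 0–2 h / 0–4 h, denser early; N = 4, σ = 0.5 nm |
| `fig3c` | composite scattering curve | p = 2.3, c = 3.9 mM, R_g = 1 nm, crossover at 0.06 Å⁻¹ fixes A; lognormal σ = 2% |

The diffused-fraction noise default (σ = 0.0177 absolute) is calibrated
analytically so the *expected* e.s.s. profile of the `fig4d` design
reproduces the reported one-sided-bound behaviour — a 1.25-fold e.s.s.
increase at K_D = 100 nM and a flat profile (< 5% change) below 1 nM —
via `ratio(K_D) = 1 + Δ(K_D)/(Nσ²)` with Δ the re-optimized systematic
misfit on the noiseless design.  A direct consequence, shared with the
real experiment, is that the best-fit K_D of any single dataset wanders
within the flat region; only the upper bound is stable.

What the generators do **not** emulate: instrument drift and
photobleaching, non-Gaussian outliers, the handling dead-time of fast
aggregation, inter-experiment pooling heterogeneity, or a mechanistic
oligomer size distribution (the co-oligomer radius is a single number,
and the `fig4b` scenario is a structural emulation with 10× secondary
nucleation, not a calibrated model of the physiological peptide).
Passing tests therefore demonstrate correctness and statistical
behaviour of the *analysis chain* under its own assumptions, not
instrument-level realism.

## Problem sizes

Defaults are desk-scale by design: 301-point kinetic grids over 30 h,
≤ 64 titration points, 250-point scattering curves, 1000–2000 bootstrap
resamples; the full test suite and the acceptance script each run in
well under a minute of CPU except the hypothesis-ranking fit (a few
seconds per hypothesis).

## Known limitations

- The fraction↔radius map is a calibrated stand-in for the vendor's
  inversion; absolute κ is instrument-specific.
- Whether the instrument averages in fraction or radius space is not
  documented; fraction-space averaging is asserted (one measured
  fraction per sample).
- K_D below ~1 nM is unidentifiable by design of the experiment; the
  package reports the profile interval rather than pretending
  otherwise.
- Seed "inactivation" scales seed mass and number together; if only
  the number of growth-competent ends were blocked, M(0) would remain
  ThT-visible — indistinguishable here because seeds contribute < 1%
  of the final signal.
- The dissociation comparison ignores the monomer-dilution difference
  between conditions (caveat attached to results).
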