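# Methods

bilayerlab analyzes molecular-dynamics trajectories of planar lipid bilayers
whose normal lies along z. This note documents the models the package
implements, the parameters that matter, what the synthetic generators do and
do not emulate, and the numerical choices made where the design was open.

## C–H bond order parameters

For each carbon–hydrogen bond the order parameter is

    S_CH = ⟨ (3 cos²θ − 1) / 2 ⟩,

where θ is the angle between the carbon→hydrogen vector and +z and the
average runs over sampled conformations. S_CH is bounded in [−0.5, 1]:
+1 for a bond locked along the normal, −0.5 for a bond locked in the
membrane plane, 0 for isotropic sampling. The antiparallel direction
convention would send θ → 180° − θ but leaves S_CH unchanged because the
second Legendre polynomial is even; the carbon→hydrogen convention is fixed,
not configurable.

Averaging is hierarchical: the time average is formed per lipid first, and
the reported mean and standard error of the mean (SEM) are taken across
lipids. Lipids are treated as independent samples; no time-correlation
correction is applied to the SEM. Frames enter the time average with equal
weight; if frame spacing is uneven a warning is logged and the unweighted
average is used anyway. A zero-length bond vector is an error naming the
offending frame, never a silent skip.

Bond identities (segment label, R/S prochirality of methylene hydrogens) are
static properties of the molecule. They are stored once in the topology,
read from a bond-definition table (TSV columns `segment_label`,
`carbon_name`, `hydrogen_name`, `stereo_label`), and never inferred from 3D
coordinates. The bundled table (`src/bilayerlab/data/popc_charmm36_bonds.tsv`)
covers POPC with CHARMM-style atom names: choline methyls (γ), headgroup
β/α, glycerol g3/g2/g1, the palmitoyl chain sn1-C2…C16 and the oleoyl chain
sn2-C2…C18. Terminal methyls and the two vinyl hydrogens carry no stereo
label. Where atom naming alone does not determine which hydrogen is pro-R,
the table's assignment (e.g. HA→R/HB→S at g3, HnX→R/HnY→S on the sn-1
chain) is a fixed convention; forking magnitudes are unaffected by swapping
it, only the sign of an R−S difference would flip.

### Forking and the electrometer response

Forking is the occurrence of unequal S_CH for the two hydrogens of one
carbon. The detector reports the magnitude |S_R − S_S| and flags
significance when it exceeds `k_sigma` combined SEMs (quadrature); the
default k_sigma = 2 corresponds to ≈95% specificity under a Gaussian null,
so on null ensembles roughly one comparison in twenty is still flagged.

The headgroup charge response is ΔS = S(c) − (S_R⁰ + S_S⁰)/2, the change of
a segment's order parameter at salt concentration c against the R/S-averaged
salt-free baseline, with the SEM propagated in quadrature (baseline terms
weighted ½). Bound positive charge at the phosphatidylcholine interface
drives the α/β ΔS negative, bound negative charge positive; the package
computes the statistic and leaves interpretation to the user.

### θ distributions

Tilt-angle histograms over [0°, 180°] are built per lipid (each lipid's
histogram normalized to unit mass, pooling its bonds and frames), then
averaged across lipids with a per-bin SEM — matching the small-subset
distributions used to visualize forking. Default 36 bins (5°).

## Density profiles and form factors

Number densities along z re-center every frame on the bilayer center —
the mean phosphorus z by default; any atom name, a fixed z, or the box
middle may be used instead — wrap into [−Lz/2, Lz/2), and accumulate counts
on a fixed grid of width 0.1 nm (default; resolves headgroup features at
desk-scale statistics). The density is counts divided by frame count and
bin volume (mean lateral area × bin width), so the profile closes exactly:
Σ density × bin volume = mean particle count per frame. Electron densities
weight each atom by its electron count, which defaults to the atomic
number; partial-charge-adjusted counts can be supplied in the topology.
Ion profiles can be rescaled to percent of the nominal salt number density
(molarity × N_A), which puts systems at different concentrations on one
axis: a bin at exactly the nominal bulk density reads 100%.

The SAXS form factor is

    |F(q_z)| = | ∫ (ρₑ(z) − ρ_bulk) e^{i q_z z} dz |,

computed by rectangle-rule quadrature over the binned profile on a q grid
in Å⁻¹ (default dq = 0.001, q_max = 1.0). ρ_bulk defaults to the mean of
the outermost 10% of bins on each side (overridable); the curve is
normalized by the maximum of |F| inside the 0.1–0.2 Å⁻¹ window — the
first-peak convention used when overlaying simulated and experimental
bilayer form factors — even when |F| is monotone there. Zero contrast in
that window raises an error rather than returning an unnormalizable curve.
The profile is transformed exactly as computed; symmetrization of ρ(z)
about the bilayer center is available behind an explicit flag, not applied
silently.

## Area per lipid, equilibration, windowing

A_L(t) = Lx·Ly/n_leaflet. Equilibration detection declares the steady state
to start at the earliest time from which every sliding window of length
span/5 keeps its mean within `tolerance_sd` (default 1) standard deviations
of the last-half mean, both reference moments taken over the last half of
the series; if no such start exists before 90% of the span the series is
flagged non-equilibrated. These parameters are heuristics of this package —
only the resulting analysis intervals are ever published in bilayer work —
and a constant series yields the full span. Non-stationary runs can instead
be split into contiguous equal windows (e.g. 10 × 100 ns for a 1 μs run)
analyzed separately; a trailing remainder is dropped with a log message,
and window endpoints are inclusive on both sides.

## Lateral diffusion

Lipid center-of-mass paths are built by unwrapping each atom across the
periodic boundary (minimal-image continuity against the previous frame;
displacements close to half a box length are logged as ambiguous), then
mass-weighting within each lipid. Optionally the per-frame displacement of
the all-lipid center of mass is subtracted, cancelling common drift;
solvent never enters this correction.

The lateral MSD is averaged over every time origin and lipid, xy components
only, evaluated directly at the requested lags (exactly equal to the naive
double-loop estimator). The default lag grid is logarithmic, 40 points
capped at half the span — stable fits at bounded cost. D_L is one quarter
of the slope of a least-squares line over the fit window, 20–50 ns when the
curve reaches 50 ns (the typically diffusive regime at these system sizes)
and [10%, 25%] of the effective span otherwise. Error bounds follow the
subgroup scheme: lipids split into five equal subgroups whose MSDs give a
per-lag SEM, and d_low/d_high are the gentlest and steepest slopes of
straight lines passing within ±1 SEM of every windowed point, found by
linear programming over (slope, intercept); if no line threads the band the
bounds fall back to the least-squares slope ± its standard error, logged.
Negative slopes clamp to zero.

Two caveats are worth stating. First, the ±1 SEM band is a heuristic, not a
confidence interval: simulated at the package's default conditions (200
lipids, 10⁴ frames at 100 ps, D = 5×10⁻¹² m²/s) it contains the true D in
roughly 87–88% of runs, so occasional misses are expected. Second, no
finite-size (periodic hydrodynamics) correction is computed;
`DiffusionEstimate.corrected(factor)` applies an externally supplied
multiplicative factor when one is available.

## Synthetic ensembles

The generators exist so every analysis stage can be validated against a
closed form without real trajectories:

* **Orientation ensembles** draw unit C–H vectors i.i.d. per frame from a
  fixed tilt (S = P₂(cos θ₀)), a uniform cone (S = cos θ₀ (1 + cos θ₀)/2,
  i.e. cos θ uniform on [cos θ₀, 1]), an isotropic distribution (S = 0), or
  mixtures (weighted sums). Azimuths are uniform. i.i.d. sampling carries
  no orientational autocorrelation, so these ensembles validate static
  observables only — nothing about relaxation or the time correlations real
  lipids show, and the SEM behaves as for truly independent frames, which
  real trajectories do not satisfy.
* **Ion slabs** draw z from interface Gaussians truncated (not reflected)
  at the box edges and renormalized analytically, plus a uniform bulk
  component; the returned truth is the exact density, so binning can be
  checked bin-by-bin against Poisson counting bands.
* **Brownian bilayers** are wrapped 2D random walks with per-axis step
  standard deviation √(2 D dt), one phosphorus-anchored site per lipid,
  optional common drift; they exercise unwrapping, COM extraction, MSD and
  the diffusion fit, but contain no sub-diffusive short-time regime, so the
  20–50 ns window is linear by construction.
* **Gaussian membranes** sample point scatterers from a Gaussian
  electron-density profile; the truth form factor is the analytic transform
  of the untruncated mixture, so peaks should sit several σ inside the box
  (truncation error is negligible below ~4σ from an edge).

All generators take a mandatory seed and are bit-reproducible; truths are
returned alongside the data so analysis-vs-truth comparisons are pure
functions of the pair.

Default study conditions used by the test-suite oracles and the acceptance
script: orientation ensembles of 200 lipids × 2000 frames; forking null
repeats of 100 lipids × 400 frames; ion slabs of a few thousand particles
over 20 frames; form-factor slabs of 10⁵ scatterers; Brownian runs of 200
lipids × 10⁴ frames at 100 ps spacing (1 μs span, matching the duration
scale of production bilayer runs) repeated 20 times.

## Units, formats, degenerate inputs

Internal units are fixed — nm, ps, unified masses, electrons — with
conversions only at I/O boundaries (MDAnalysis Å → nm on read, nm → Å on
write; q reported in Å⁻¹). GRO/PDB topologies and XTC/TRR/DCD trajectories
are supported; non-orthorhombic boxes are rejected, not approximated. A
plain-text fixture dialect (header `n_atoms n_frames`, then per frame a box
line and xyz records) supports dependency-light tests; it carries no clock,
so uniform 10 ps spacing is assumed on load. Degenerate inputs fail loudly:
zero-length bond vectors, flat bilayers (all anchors at one z), empty
selections, zero-contrast form factors, windows selecting no frames, and
subgroup splits that do not divide the lipid count all raise typed errors.
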