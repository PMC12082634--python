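# Methods

This note documents the models implemented in scramblekit, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Flip-flop detection

A lipid's orientation is the transverse separation of its headgroup and
terminal-tail beads, Δz = z_head − z_tail, with the minimum image applied
in z.  The instantaneous state is *upper* for Δz ≥ d, *lower* for
Δz ≤ −d, and *undetermined* otherwise; the default threshold d = 2.1 nm is
the value at which flip-flop counts in coarse-grained translocon membranes
plateau (roughly over 2.1–2.4 nm), and `threshold_scan` reproduces that
plateau analysis on any trajectory.  The *assigned* leaflet is initialized
from the head's side of the membrane midplane at the first frame and
thereafter changes only when the instantaneous state reaches the opposite
leaflet.  This hysteresis is an implementation choice: without it, a lipid
dwelling near the midplane would rack up spurious events, and with it an
event requires one full crossing, matching the operational definition of a
flip-flop as a change of assigned leaflet.  The timestamp of an event is
the first frame of the new assignment, and the "initiation point" used for
pathway attribution is the head position at that frame.

Sign convention: head-above-tail is taken to mean *upper leaflet*, which is
the geometrically natural reading; a `leaflet_sign` switch inverts it.
Event counts and rates are invariant to this choice because the criterion
is symmetric in |Δz|.

Events are attributed to the protein site whose pathway beads have the
smallest 3D minimum-image distance to the event's head position, provided
it is within the cutoff (default 2.0 nm); ties break by distance and then
site name, and everything else is "bulk".

## Rate statistics

For each (site, lipid type), the rate is the mean over replicas of
events/duration (1/μs), with the standard error taken across replicas
(sample SD/√n) — the convention used for tabulated scrambling rates.  The
per-site total row sums the per-type rates, with its SE computed from the
per-replica grand totals so correlations between types are respected.
Group comparisons use a two-sided Welch t-test on the per-replica rates;
this test was chosen for robustness to unequal variances, and the package
makes no attempt to reproduce any particular published p-value, since
summary rates alone do not determine the test.

Arrhenius analysis fits ln k against 1/T by ordinary least squares and
reports E_A = −slope·R.  Unweighted OLS is the default: on the 290–330 K
reference rate series (1.7, 3.3, 7.7, 14.3, 26.0 lipids/μs) it yields
E_A = 55.1 kJ/mol, consistent with the reported ≈55.3 kJ/mol, whereas
inverse-variance weighting by the relative errors (SE/k)² is available as
a mode (`weighted=True`) and yields ≈53.8 kJ/mol on the same data.  The
Eyring helpers implement k = κ(k_B T/h)exp(−G‡/RT) with κ = 1 by default
and the derived fold change exp((ΔG_ref − ΔG_new)/RT).

## Free-energy profiles

Headgroup densities are histogrammed along z *relative to the per-frame
centroid of a protein reference group* (the membrane fluctuates; the
protein frame removes the drift), into 300 slices spanning the box height
by default, and converted to number density.  Boltzmann inversion gives
ΔG(z) = −RT ln(ρ(z)/ρ₀) with ρ₀ the maximum density, so the global
minimum is exactly zero; where the two leaflet minima differ, the deeper
one sets the zero.  Zero-density bins become +∞ and are never
interpolated: if they occur between the sampled flanks the profile is
flagged `unsampled_core` and any barrier read from it is a lower bound.
Silent interpolation would fabricate barrier heights, so it is refused.

The barrier is the maximum of ΔG between the two minima found on either
side of the grid midpoint.  Two error estimates are implemented: the
leaflet-asymmetry error |ΔG(z*) − ΔG(−z*)| at the barrier (suitable for a
symmetric protein-free system) and the SD of replica profiles evaluated at
the barrier position.

### Entropy/enthalpy decomposition

Profiles measured at several temperatures are combined by finite
differences assuming the entropy is constant across each temperature pair:
ΔS(z) = −[ΔG(z,T₂) − ΔG(z,T₁)]/(T₂ − T₁) and
ΔH(z) = ΔG(z,T_mid) + T_mid·ΔS(z), evaluated for the pairs (300, 320) K
and (290, 330) K and reported at T_mid = 310 K as the mean of the two pair
estimates with their absolute difference as the error.  By construction
ΔG = ΔH − TΔS holds pointwise at T_mid.  The two source descriptions of
this scheme disagree on whether the *entropy* or the *enthalpy* is held
constant over the window; the finite-difference form above (constant
entropy within a pair) is the standard construction and is what is
implemented, validated against linear-in-temperature profile families for
which it is exact.

Profiles are linearly resampled onto the T_mid grid when grids differ
(tolerance 1e-6 nm).  Externally computed PMFs (e.g. AWH output in XVG
format) enter through `read_tabular_profile` and are treated identically
downstream; the biased simulation itself is out of scope.

### Thickness–barrier trend

`fit_thickness_barrier` fits a least-squares line to (thickness, barrier)
pairs from reference bilayers, and `predict_barrier_reduction` reads the
barrier lowering implied by a local thinning as the vertical separation of
the fitted line between the bulk and local thickness values.

## Membrane maps

Thickness is the local interleaflet distance of the headgroup beads: on an
xy grid (default 0.2 nm spacing, configurable — the bead scale of
coarse-grained membranes), mean upper-leaflet head z minus mean
lower-leaflet head z accumulated over frames, using the leaflet
assignments from the detector.  Cells that never sample both leaflets are
undefined (NaN), never zero.  Leaflet means per cell were preferred over
nearest-pair distances because they are robust at low per-cell counts.

Lipid environments partition every lipid-frame exhaustively: within 2 nm
of a site's beads → that site (nearest wins), at least 3 nm from all
protein beads → bulk, otherwise → intermediate.  The explicit intermediate
class exists because the 2 nm/3 nm rules leave a gap.

Volumetric densities are voxel counts (default 0.2 nm voxels) of selected
beads in the protein frame, normalized by frames × voxel volume and
averaged over replicas; the normalization is exact bookkeeping
(Σρ·V_voxel·frames = observations).  Pathway continuity thresholds the
map and labels 26-connected components; the pathway is continuous when one
component touches both leaflet planes.  The verdict is monotone in the
threshold.  A practical threshold is ~10% of the bulk-headgroup plateau
density, and it is always reported alongside the verdict.

## Assay model

The dithionite and BSA assays are modelled with the minimal two-compartment
mechanism that reproduces their endpoint logic: label fractions N_out and
N_in exchange symmetrically at the scrambling rate k_scr, the quencher
converts outer-accessible labels to a quenched pool at k_q after the
addition time, and the fluorescence read-out is
F = N_out + N_in + c·Q with c = 0 (dithionite renders labels dark) or
c = 0.5 (BSA quenches at most half of the accessible NBD fluorescence).
This yields the closed-form plateaus 0.50 (dithionite, no scrambling),
0.0 (dithionite, complete), 0.75 (BSA, none) and 0.50 (BSA, complete).
Measured protein-containing dithionite curves often level off above zero;
an optional non-scrambling vesicle fraction reproduces such residuals, but
slow fluorophore dimming is deliberately not modelled, so the residual
level is not a fitted constant of the package.

Decays are normalized by the pre-addition mean and shifted so the decay
starts at (0, 1), which is what makes the constraint F_s + F_f = 1 of the
double-exponential fit F(t) = F_s e^(−t/τ_s) + F_f e^(−t/τ_f) exact.  The
fit builds the constraint into the parameterization, multi-starts from
five log-spaced time constants, orders slow/fast on output, and flags
(rather than penalizes) degenerate fits where the two time constants
collapse — a plateaued curve is legitimately described by τ_s → ∞.

## Synthetic generator

The generator emulates the study geometry: a 15×15×12 nm box with 600
POPC lipids (300 per leaflet), head planes ±2.0 nm from the midplane, tail
beads 1.0 nm on the opposite side (so |Δz| ≈ 3 nm in a leaflet and the
2.1 nm criterion sits in a wide clean margin), transverse fluctuation
σ_z = 0.3 nm, lateral random walk 0.1 nm/frame, 20 μs at 1 ns spacing,
310 K.  Flip-flops arrive as independent Poisson processes per
(lipid type, site) at the specified system rate in 1/μs; the flipping
lipid jumps to within 1 nm of its site center (making the 2 nm pathway
attribution testable against truth) and its beads traverse their planes
linearly over a 50 ns transit.  The linear transit is the simplest path
that exercises the detector's hysteresis; no microscopic flip path is
asserted.  Overlapping events on one lipid queue after the current
transit, never dropped.  Protein sites are static five-bead columns
spanning the membrane — the honest analogue of a backbone-restrained
complex — and double as the membrane-frame reference.  Per-lipid RNG
streams are counter-based (seeded by (seed, lipid index)) so adding lipids
never perturbs existing streams; identical specs reproduce trajectories
bit for bit.

What the generator does *not* emulate: force-field energetics, lateral
phase behaviour or crowding, protein internal motion, membrane
undulations, or any correlation between consecutive flip times beyond the
queueing rule.  Tests passing on this data demonstrate that the estimators
are correct and unbiased under their own model assumptions — not that the
detector is robust to, e.g., strongly undulating membranes.

## Problem sizes and numerical choices in the test suite

Recovery tests run at the study scale they emulate: five 20 μs replicas of
600 lipids at 2 ns frame spacing for rate recovery (the estimator is
compared to truth within 3 SE, with the exact Poisson sd as a floor), and
10⁶ draws for the free-energy round trip.  The synthetic PMF used for that
round trip is a compact double well (barrier 20 kJ/mol at z = 0, wells at
z = ±0.5 nm, 0.1 nm grid): with diffuse wells the barrier bins of a 10⁶
sample histogram would hold only a handful of counts and the comparison
would measure shot noise rather than the inversion, so the fixture
concentrates the equilibrium population to keep the barrier-bin occupancy
at O(100) counts.  Sampling is inverse-CDF on the profile grid with
uniform in-bin jitter, which makes the discrete round trip unbiased by
construction.  Double-exponential recovery uses 100 noise seeds at
σ = 0.005 on 240-point curves.  Connectivity verdicts are cross-checked
against a brute-force flood-fill oracle on random voxel fields.

## Known limitations

- Orthorhombic boxes only; triclinic inputs are rejected explicitly.
- Coordinates are stored wrapped; molecules are not made whole, so the
  head/tail separation relies on the minimum image in z.
- The density-based profile cannot resolve barriers in regions that are
  never sampled; such profiles are flagged and give lower bounds.
- The assay model has no dithionite permeation, photobleaching,
  inner-filter effects, or vesicle size distribution; per-lipid quench
  rates stand in for headgroup-specific quencher kinetics.
- g_lomepro-style spectral filtering of thickness maps is not implemented;
  the grid-mean estimator agrees with it only qualitatively.
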