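# scramblekit

Analysis toolkit for quantifying **lipid scrambling** — protein-assisted
flip-flop of phospholipids between bilayer leaflets — from coarse-grained
membrane simulations and from fluorescence scrambling assays.  It targets
systems like the Sec61/TRAP translocon, where polar trans-membrane crevices
let lipid head groups slide between leaflets (the "credit card" mechanism),
but every component works on any head/tail bead-pair membrane model.

## What it computes

- **Flip-flop kinetics.** A lipid's orientation is read from the transverse
  head-tail separation Δz = z_head − z_tail; |Δz| ≥ d (default d = 2.1 nm)
  puts it in a leaflet, and the assigned leaflet carries hysteresis so an
  event is only counted on a full crossing.  Events are attributed to named
  protein sites when they initiate within 2 nm of the site's pathway beads.
  Rates are reported per lipid type and site in lipids/μs with
  replica-to-replica standard errors, plus threshold-sensitivity scans,
  Welch tests between systems, the Arrhenius fit
  ln k = ln A − E_A/(R T), and Eyring speed-ups
  exp(ΔΔG‡/R T) with k = κ (k_B T/h) exp(−G‡/R T).
- **Free-energy profiles.** ΔG(z) = −RT ln(ρ(z)/ρ₀) from headgroup number
  densities histogrammed in a protein-fixed frame (300 slices by default),
  barrier extraction with leaflet-asymmetry or replica errors, import of
  externally computed PMFs, and enthalpy/entropy decomposition by finite
  differences over temperature pairs (300/320 K and 290/330 K), reported at
  310 K with the pair disagreement as the error.
- **Membrane maps.** Local interleaflet phosphate-distance (thickness) maps
  on an xy grid, lipid-environment classification by the 2 nm / 3 nm
  distance rules, 3D volumetric headgroup densities, and a 26-connected
  continuity test for scrambling pathways bridging the leaflet planes.
- **Scrambling assays.** A two-compartment forward model of the dithionite
  and BSA back-extraction assays (plateaus 0.50/0.0 and 0.75/0.50 for
  no/complete scrambling), curve normalization, and the constrained
  double-exponential fit F(t) = F_s e^(−t/τ_s) + F_f e^(−t/τ_f) with
  F_s + F_f = 1.
- **Synthetic ground truth.** A generator producing head/tail bead-pair
  trajectories with Poisson flip-flop events localized at named sites,
  Arrhenius temperature series, Boltzmann samples from a prescribed PMF,
  and noisy assay curves — every analysis stage is testable against known
  truth without any external data.

Units package-wide: nm, ns, K, kJ/mol; rates in 1/μs; assay times in s.

## Worked example

```python
import scramblekit as sk

spec = sk.SyntheticSpec(
    n_per_leaflet={"POPC": 100}, n_frames=5001, dt_ns=2.0,
    flip_rates={"POPC": {"Sec61": 2.0, "TRAP": 1.0}}, seed=42,
)
traj, lipids, sites, truth = sk.generate_trajectory(spec)
states = sk.assign_leaflets(traj, lipids, threshold=2.1)
events = sk.assign_events_to_sites(
    sk.detect_events(states, traj, lipids), sites, traj, cutoff=2.0)
print(sk.compute_rates([events], [spec.duration_us]).formatted())
```

prints (`examples/01_flipflop_detection.py`)

```
 site lipid_type      rate  n_replicas  total_events
Sec61       POPC 1.8 ± 0.0           1            18
Sec61      total 1.8 ± 0.0           1            18
 TRAP       POPC 1.0 ± 0.0           1            10
 TRAP      total 1.0 ± 0.0           1            10
```

i.e. all 28 true events were detected and attributed: the Sec61 site
scrambles 1.8 lipids/μs (truth 2.0, within Poisson noise of 18 counts) and
the TRAP site 1.0 lipids/μs.  The Arrhenius/Eyring example prints
`E_A = 55.1 ± 1.5 kJ/mol` for the 290–330 K rate series (1.7, 3.3, 7.7,
14.3, 26.0 lipids/μs) and a 2.46×10⁸-fold speed-up when the flip-flop
barrier drops from 59.2 to 9.4 kJ/mol at 310 K — a month-scale half-life
becomes ~11 ms.

The `examples/` directory holds one short script per capability
(detection, Arrhenius/Eyring, free-energy profiles, membrane maps, assay
fitting); each prints what it computes and what the numbers mean.

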