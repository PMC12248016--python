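# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying experiment
or simulation protocol leaves the convention open.

## Trajectory observables

**Hydrogen bonds.** An edge between two oxygens (water–water or
water–protein) requires donor–acceptor distance ≤ 3.5 Å **and**
donor–H–acceptor angle ≥ 150°; both cutoffs are configurable
(`AnalysisConfig`). These are standard water hydrogen-bond criteria; no
universally agreed values exist, so the choice is declared rather than
inferred. Protein N/O atoms participate as acceptors only (the reference
scaffold carries no protein hydrogens). A water lacking hydrogens can
optionally fall back to a distance-only test (off by default, logged
when used). Waters inside a solution compartment (z-slabs of half-width
12 Å about the membrane midplane by default) gain an edge to that
compartment's pseudo-node; compartments are disjoint by construction.

**Water-wire classes.** A wire is a path in the per-frame hydrogen-bond
graph from a protein source site to the intracellular compartment node.
Classes are declared, configurable waypoint rules rather than geometric
heuristics: class 1 starts at the anion-pathway markers (inner-gate
S107 OG / Y445 OH, adjacent to the central and internal anion sites);
classes 2 and 3 start at the gating-glutamate (E148) carboxylate oxygens
and are split by whether the path passes within 4 Å of the E203
(Glu_in) carboxylate — class 2 crosses that proton-pathway segment,
class 3 avoids it. "Requires a waypoint" is evaluated as: some water
near the waypoint is reachable from the source *and* reaches the sink;
"avoids" removes the waypoint-adjacent waters before testing
connectivity. Reported paths are shortest paths (hop count).

**Ion-leaving events.** The per-subunit series d(t) is the Euclidean
distance from the Y445 Cα (configurable) to the nearest Cl⁻, ties broken
to the lowest atom id; frames without ions record +inf and flag the
series. The series is smoothed with a centered moving average (20 ns
window, shrinking at the edges). An event is called at the first time
the smoothed distance exceeds 12 Å and stays above it for at least the
dwell time (50 ns default) or to the trajectory end; trajectories
shorter than the dwell window return "indeterminate". The dwell rule is
a robustness choice — it suppresses single-frame spikes that survive
light smoothing — and is not part of the threshold definition itself.
The exit side is the sign of the ion's z coordinate (membrane midplane
at z = 0) at the first *raw* threshold crossing; the smoothed onset can
precede physical departure by up to half the smoothing window, so the
raw series is the right place to read the geometry.

**Gate state.** Open when the S107 OG – Y445 OH separation exceeds
6 Å (configurable); no hysteresis by default.

**Occupancy statistics.** Per-simulation wire occupancy is the fraction
of frames containing any wire. Box statistics across simulations use
linear-interpolation quartiles (numpy's default percentile convention —
stated here because box plots depend on it) and whiskers at the last
data points within 1.5× the interquartile range.

**Periodic boundaries.** No imaging is performed inside detectors;
trajectories must be pre-imaged. The reader warns when frame-to-frame
displacements exceed half the box.

## Synthetic trajectories

The generator builds a minimal two-subunit scaffold — Cα and one
side-chain reference atom for S107, E113, K131, E148, E203, F357 and
Y445 on chains A and B, 60 Å apart — not a full transporter model.
Every detector depends only on these declared reference atoms, which is
what makes the stand-in faithful: passing tests demonstrate that the
detectors recover planted geometry, not that they would segment a real
123,000-atom membrane system (no lipids, no crowded solvent, no
force-field dynamics, no periodic box).

Planted wires are water chains with 2.8 Å O–O spacing and ≥ 160°
donor angles, comfortably inside the 3.5 Å / 150° detection cutoffs so
generator and detector thresholds stay decoupled. Chain routes are laid
out so the three classes are geometrically independent (no chain passes
within the hydrogen-bond cutoff of another class's source or waypoint).
Topology is fixed across frames, so each planted wire owns its waters
and parks them in a far-away lateral band outside its episode frames.
Leaving events displace both of a subunit's ions monotonically past
12 Å from the Y445 Cα toward the planted exit side; gate-open episodes
step the Y445 OH to an 8 Å separation. Positional noise is isotropic
Gaussian on every atom; the documented noise level for recovery suites
is σ = 0.05 Å, at which the planted 0.7 Å geometric margins are ≈ 10σ,
and recovery is required in ≥ 95% of 100 seeds (exact at σ = 0).
Frames are spaced 0.2 ns (the 200 ps save interval of the emulated
production runs).

## HDX-MS analysis

Exchange is treated as purely base-catalyzed across pH 3.0–6.5: the
intrinsic rate scales as 10^(ΔpH), which is exactly the 100-fold
(2 units) and 10-fold (1 unit) time matching the experimental design
uses; no acid-catalyzed minimum correction is applied, and the
deviation from a full intrinsic-rate calculation is deliberate and
confined to this stated regime. Matched time points pair raw times
whose normalized times agree within 5% (relative), each used at most
once.

Exchangeable amides per peptide: N_ex = length − 2 − (prolines at
positions ≥ 3) — the common HDX convention (N-terminal residue plus the
fast-back-exchanging first position after cleavage excluded, prolines
lacking amide protons) — configurable, since reference software
conventions differ. Back-exchange correction is multiplicative per
peptide, D_corr = D_raw·N_ex/D_FD; peptides with non-positive FD
control are excluded and logged. Differential maps are computed on the
corrected scale, replicate means first, with per-cell SD propagated
where replicates exist (the emulated design triplicates 20 s, 633 s and
20,000 s). Per-residue painting spreads peptide values by averaging
overlapping peptides.

The synthetic uptake law is per-residue two-parameter kinetics,
uptake = β·(1 − exp(−k_int(pH)·t/P_r)) summed over exchangeable
residues, with β the back-exchange retention factor and P_r ≥ 1 a
protection factor. Protection factors are synthetic knobs, not
estimates of real per-residue CLC-ec1 values; parameter-recovery tests
place them so the corresponding half-lives fall inside the labeling
grid (a rate outside the observed window is unidentifiable from any
fit).

## Flux assays

Rates are initial slopes: a linear fit over a window after valinomycin
addition minus the slope over a pre-valinomycin baseline window (leak
correction); 30 s / 30 s by default, extended (120 s fit, 60 s baseline,
with doubled reconstituted protein) when emulating slow mutants, as one
would at a tenfold-lower signal. The H⁺ trace is recorded as
extravesicular pH and inverted through a stated buffer capacity
(mol H⁺·pH⁻¹·L⁻¹): uptake into vesicles removes H⁺ from the measured
solution, so the recorded pH rises. "Per transporter" means per
homodimer with a default molar mass of 100 kDa — the convention is
genuinely open, and the stoichiometry is invariant to it since the
transporter count cancels in the ratio. Stoichiometry is computed per
replicate and summarized as mean ± SEM. Chloride traces are consumed
already calibrated to mM; a Nernstian two-point calibration is out of
scope for the generator.

## ITC

Heats follow the single-site Wiseman isotherm in the total-ligand
formulation with displaced-volume dilution (cell concentrations diluted
by (1 − ΔV/2V₀)/(1 + ΔV/2V₀), differential heats corrected by
(dVᵢ/V₀)·(Qᵢ+Qᵢ₋₁)/2). Fitting is least squares over (log₁₀ Kd, ΔH,
baseline) with n fixed at 1 and multistart over log-Kd; reference
(buffer-into-protein) heats are subtracted when provided. The
no-heat-detected rule compares the heat sequence's departure from its
best linear (dilution-like) trend with k× the instrument noise
(k = 5; noise supplied or estimated from the titration tail). A
threshold on the c-value alone would misclassify informative low-c
titrations (a 1 mM Kd at a 15 µM cell has c ≈ 0.015 yet a clearly
curved, recoverable isotherm), so c is computed and reported but does
not by itself trigger n.h.d.; on n.h.d. the reported Kd lower bound is
the c = 0.1 detectability bound n·[cell]/0.1.

## Exchange-cycle simulator

The transport cycle is a five-state kinetic loop (gating-glutamate
"up" A → protonated "out" B → transient anion-pathway entry C →
single-occupancy "down" D and "middle" E → back to A on Cl⁻ entry from
the inside). Translocation is bookkept with per-transition tags,
credited when a translocation completes: the proton loaded from the
outside (A→B) is counted at its intracellular release (B→C), and the
two Cl⁻ release steps (C→D, D→E) each count one ion out. Summed around
the loop the tags give exactly (2 Cl⁻ out, 1 H⁺ in) — validated at
model construction — so the ratio counted per completed cycle is a
rate-independent identity, and the cycle nets three elementary charges.
Cl⁻ release is sequential by default; a concerted two-ion release
variant is provided. Rates default to 100 s⁻¹ forward / 10 s⁻¹ reverse
(net forward driving); since the per-cycle stoichiometry is
rate-independent, these defaults affect only convergence speed.

The off-cycle (K131-like) variant adds, from the single-occupancy
states D and E, a two-step excursion: the weakly bound Cl⁻ leaks out of
the pathway *down-gradient* (tagged +1 Cl⁻ in the transport direction,
no H⁺) into an empty-pathway state, which then refills from the
opposite side (tag 0, fast). Each completed excursion therefore adds
one uncoupled Cl⁻ translocation, making the long-run ratio
2 + E[off-cycle events per cycle]; a leak tagged against the transport
direction would instead drive the ratio toward 1, which is not what
experimental uncoupling (ratios rising from 2 toward 3) looks like.
The branch rate is tuned analytically: the stationary distribution of
the generator matrix gives the off-cycle flux per cycle flux, and the
rate achieving a requested expectation (one per cycle for the ≈3:1
regime) is found by root-finding. Under inverted driving
(forward/reverse roles swapped) the leak follows the inverted gradient
and is re-tuned against the backward flux.

Simulation is exact CTMC (Gillespie) sampling, deterministic given the
seed, with runs terminated at returns to the start state so that all
reported counts are over closed walks (where the tag-sum identities are
exact). The transition log is sufficient to replay every counter.

## Problem sizes

Default test and acceptance runs use 10,000 completed cycles for
stoichiometry estimates (sampling error ≈ 0.5% on the 3:1 ratio),
100-seed recovery suites for wires, leaving events, flux stoichiometry
and ITC, and synthetic trajectories of 12–400 frames with two subunits.
These sizes give comfortable statistical resolution for every asserted
tolerance while keeping the full suite in the minutes range on one CPU.

## Known limitations

* The trajectory stand-in validates detector logic, not behavior on
  real MD output; applying the detectors to genuine trajectories
  requires pre-imaged coordinates and may need the configurable cutoffs
  revisited.
* Wire classification by waypoint sets is a declared operationalization;
  other published analyses may partition wires differently.
* The pH-normalization law ignores acid-catalyzed exchange, valid only
  in the base-catalyzed regime used here.
* The cycle model has no ligand-concentration dependence (lumped
  pseudo-first-order rates); gradient reversal is modeled by swapping
  forward/reverse rate roles, not by thermodynamic box constraints.
* Poisson statistics of protein-per-vesicle occupancy, vesicle size
  distributions and electrode response kinetics are not modeled.
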