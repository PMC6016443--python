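# Methods

This note documents the models behind each analysis, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that were genuinely open.

## Molecular model

Structures are annotated `Topology` objects (per-atom charge,
Lennard-Jones ε and R_min/2, hydrogen-bond donor/acceptor flags,
molecule/chain/side-arm grouping) plus `Frame`s carrying N×3 coordinates
in Å and an orthorhombic box. Chemistry comes from a user-editable CSV
keyed on (residue name, atom name); atoms absent from the table are
flagged `OTHER` with zero charge/LJ and a warning, so an incomplete
table degrades loudly rather than silently. Only orthorhombic cells are
supported — the systems of interest are rectangular bilayer patches —
and triclinic input raises immediately.

Two structural conventions are load-bearing and shared with the
generator: a hydrogen belongs to the nearest preceding heavy atom in
the same residue, and polymer monomers are delimited by the backbone
bead `CB` (side-arm ids count `CB` occurrences). Both survive a PDB
round trip, which preserves names and coordinates to the format's
3-decimal precision.

Distances use the minimum-image convention throughout; 2-D densities
use coordinates wrapped into [0, L). Whether the original analyses used
wrapped or unwrapped coordinates is not documented anywhere we could
check, so this choice is stated here rather than claimed as a
reproduction.

## Hydrogen bonds

A donor-H···acceptor triple is a bond when d(D···A) ≤ d_max (default
4.0 Å) and the deviation of ∠D–H–A from 180° is ≤ a_max (default 60°),
both inclusive. The criterion is conventionally quoted as
"donor–H–acceptor angle ≤ 60°"; taken literally that angle is
geometrically near-impossible for a bonded hydrogen, so the default
reads it as deviation from linearity (∠D–H–A ≥ 120°), the standard
MD-analysis convention. The literal reading stays available via
`angle_convention="literal"`. Each hydrogen on a donor is tested
independently, but one donor–acceptor pair yields at most one record
per frame (best-angle hydrogen), keeping counts comparable to standard
tools; whether the original counts were per-pair or per-hydrogen is
unknown, so the convention is documented and switchable rather than
asserted. Candidate pairs come from a grid-accelerated neighbour search
with distances recomputed in float64, so results are identical to an
exhaustive all-pairs scan (tested record-for-record on 50 random
planted systems).

Uncertainties on per-frame counts use block averaging (5 contiguous
blocks by default) to tolerate frame-to-frame correlation.

## Membrane organization

Leaflets are assigned by the sign of phosphate z minus the mean
phosphate z; exact ties go to "upper" with a warning. g(r) uses the
standard normalization (pair histogram / shell volume / ideal density /
N_A / frames) with defaults dr = 0.1 Å and r_max = 12 Å — small enough
to respect the half-box constraint on any sensible patch, fine enough
to resolve hydrogen-bonding first peaks; neither value is prescribed by
anything, both are configurable. The ideal-gas limit (mean g within
1 ± 0.05 on 5–15 Å at N = 5000) and the simple-cubic first-shell
coordination number (exactly 6) serve as analytic anchors.

2-D number densities are computed per leaflet from one representative
bead per molecule (phosphate for lipids; any bead set the caller picks
for polymers — the demo uses backbone beads). The default grid spacing
in the demo pipeline is 8 Å, roughly one cell per lipid: molecule-
position maps carry no information below the inter-lipid spacing, and
finer grids make the Pearson colocalization of two point patterns an
artifact of which sub-lipid cell each bead lands in.

"Sequestered side arm" has no published operational definition; here an
arm is sequestered iff any of its heavy atoms lies strictly below the
upper-leaflet mean phosphate plane (configurable offset). This matches
the insertion language used when such counts are reported, is exactly
testable, and is monotone under lowering an arm.

Conformation metrics (R_g, end-to-end, in-plane extent, head-group
contacts within 4 Å) are computed on unwrapped coordinates, assuming
chains do not straddle the periodic boundary — true for the generator
and for any recentred trajectory. A chain is labelled "extended" when
its mean R_g is ≥ 0.75 of the ideal straight-rod R_g of its backbone
(b·√((n²−1)/12) for n beads at spacing b); the fraction is a knob.

## Interaction energetics

Electrostatic (C·q_iq_j/r with C = 332.0636 kcal·Å·mol⁻¹·e⁻²) and
Lennard-Jones (CHARMM form and combination rules) pair sums are
truncated with the CHARMM cubic switching function between 10 and 12 Å
— the scheme the underlying simulations used for LJ. Electrostatics are
switched-cutoff too, *not* mesh Ewald: a per-group energy decomposition
is only well defined without reciprocal-space terms, so long-range mesh
contributions are deliberately absent. This is a deviation by necessity
and means absolute electrostatic magnitudes are not comparable to
PME-based totals; relative comparisons between polymer chemistries at
fixed geometry are.

Contributions are summed in sorted order, making the result independent
of pair enumeration order (so swapping the groups is exactly
symmetric). Totals are normalized per sequestered side arm using the
frame-wise count (time average of the ratio, frames with zero arms
excluded); a final-frame-divisor mode exists because the original
choice is unknowable. Zero sequestered arms in every frame leaves the
per-arm fields `None` rather than inventing a number.

## Binding thermodynamics

The one-set-of-sites isotherm uses the physical root of the mass-
balance quadratic for bound titrant, with perfusion-cell bookkeeping:
injections displace well-mixed cell liquid, so after cumulative
injected volume ΔV the cell species is M₀·exp(−ΔV/V₀) and accumulated
titrant X₀·(1 − exp(−ΔV/V₀)); the observed heat adds back half the heat
content carried out by the displaced volume. In the strong-binding
limit this bookkeeping conserves mass exactly: each pre-saturation
injection releases ΔH × (moles injected), and the cumulative heat
approaches n·M₀·V₀·ΔH (verified to 1%, the residual being the discrete-
vs-continuous dilution difference). Default cell volume is 1.4285 mL
(the MicroCal VP-ITC class) and the default schedule is 40 injections
of 5 μL with a 2 μL priming shot.

The titration modelled is reverse — lipid titrated into polymer — so
the fitted stoichiometry n is lipids per polymer. Default
concentrations are 1 mM lipid in the syringe and a lipid:polymer molar
ratio of 30:1 for the cell (0.0333 mM). The quaternized polymer's molar
mass is not well defined (only the ~6000 Da precursor is), so the
working molar ratio, which the experimental protocol states directly,
fixes the default; `polymer_molarity_mM` converts a mass concentration
through a Mw knob for users who prefer that route. The fitted n for
real data inherits whatever concentration convention was used and
should not be over-interpreted.

The fit optimizes (n, log₁₀K_a, ΔH) by least squares (optionally plus a
constant offset), subtracts a buffer control first when one is
attached, and excludes the priming injection by default. Essentially
constant heats trigger an explicit "K_a unidentifiable" warning. ΔG and
ΔS derive from the identity ΔG = −RT ln(55.5·K_a) = ΔH − TΔS with
R = 1.986 cal mol⁻¹ K⁻¹ and T defaulting to 310.15 K; by construction
the two routes agree to machine precision. `saturation_fraction` below
0.9 at the final injection operationalizes an "incomplete" titration.

Laurdan GP reads I₄₄₀ and I₄₉₀ off the emission spectrum by linear
interpolation; it is scale-invariant and bounded by [−1, 1] for
non-negative spectra.

## Vibrational spectra

Baselines are low-order polynomials fitted with iterative clipping of
points more than 2σ *above* the fit (peaks are one-sided in Raman).
Peaks are Lorentzians — the standard line shape for molecular Raman
modes — with Gaussian available behind a flag; fits run on lmfit with
centers bounded to the window and widths kept positive.

Doublet splitting is a model-selection problem that a pure residual
comparison always decides in favour of more peaks, so the two-peak
model must win decisively — ΔAICc > 10, the conventional "essentially
no support" threshold for the losing model — *and* produce a physically
resolvable doublet: separation > 2 cm⁻¹ (the grid/linewidth-limited
resolvable separation; a knob), both components ≥ 2 cm⁻¹ wide (rejects
single-pixel spikes) and a component height ratio ≥ 0.1 (rejects
vanishing satellites). On synthetic singlets at SNR 20 this combination
measures a 0/100 false-positive rate while detecting 99/100 planted
1096/1100 cm⁻¹ doublets with 3:2 amplitudes.

Mode shifts are differences of fitted centers (negative = softening)
and antisymmetric under swapping reference and treated spectra. Band
emergence integrates the baseline-corrected band window (default
1660–1700 cm⁻¹) per temperature without rectification, estimates the
per-point noise robustly (1.4826×MAD, insensitive to the sparse peaks),
and declares the transition at the first temperature whose area exceeds
the low-temperature mean by 3× the larger of the low-T spread and the
propagated area noise. A band present at every temperature reports the
lowest one with a warning; a band present at none reports no
transition. A logistic fit supplies an independent midpoint estimate.

## Synthetic systems: what they are and are not

Pseudo-lipids are coarse beads — phosphate + two acceptor oxygens,
a PE ammonium donor or PG hydroxyls, two tails — on jittered leaflet
grids (default area 70 Å² per lipid, head planes 38 Å apart), with PG
lipids assigned to the grid sites nearest planted cluster centers.
Polymers are bead strings (12 monomers, 3 Å backbone spacing) with
per-monomer cationic side arms whose hydrogen-bonding bead is an N–H
donor (amide), a carbonyl acceptor (ester, with the same charge
magnitudes as the amide) or inert (hexyl); chains start 12–18 Å above
the upper leaflet. Default composition, 90 PE + 38 PG with four
12-monomer chains, mirrors the simulated patch these analyses are meant
for.

Hydrogen-bond planting moves k arms into donor–acceptor geometries 1 Å
inside the distance cutoff and ~38° inside the angle cutoff, while
every non-planted polymer↔lipid donor/acceptor pair stays ≥ 0.5 Å
*outside* the distance cutoff; the margin guarantee is scoped to
polymer↔lipid pairs — the pairs the detector is run on — not to
intra-lipid geometry. Side-arm insertion lowers chosen arms below the
phosphate plane, snapped laterally to gaps between lipids; inserted
poses are for energy/conformation analyses and carry no H-bond margin
guarantee. The bundled demo poses encode the expected
amide > ester > hexyl contrast (more planted bonds, deeper insertion,
chains over the PG clusters) *by construction*: the pipeline's
comparison report is a smoke test of the machinery, not evidence about
real polymers.

What the generator does not emulate: thermal disorder and sampling
noise of real trajectories, realistic lipid force fields or packing,
water and ions, membrane curvature or undulations, polymer
conformational ensembles, and any instrument response beyond additive
Gaussian noise on spectra and heats. Passing tests therefore certify
the correctness of the analysis arithmetic and detection logic under
known ground truth — not that real systems will show these magnitudes.

## Problem sizes

The test suite and acceptance script run desk-scale studies chosen to
make the statistics decisive: 50 planted systems (~1200 atoms each) for
oracle equivalence, N = 5000 for the ideal-gas g(r), 100 Monte-Carlo
seeds for noisy ITC recovery and for the splitting false-positive rate,
20 seeds for spectral center recoveries, and 16 temperatures for band
emergence. Stochastic recovery tolerances (e.g. doublet centers within
0.5 cm⁻¹ at SNR 20) are asserted on medians over seeds; per-draw bounds
would be violated by ordinary noise fluctuations at the stated SNR.

## Known limitations

* Switched-cutoff electrostatics (no PME) — see above.
* Orthorhombic boxes only.
* No hydrogen-bond lifetime/autocorrelation analysis; no lipid order
  parameters or area-per-lipid time series.
* The ITC model is single-class independent sites; multi-site,
  sequential and competitive schemes are out of scope.
* DCD input is supported through the structure reader's backend, but
  the text-based formats (multi-model PDB, XYZ with a box comment) are
  the tested paths.
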