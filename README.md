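# memint

Quantitative analysis of cationic-amphiphilic polymer / lipid-bilayer
interactions.

Antimicrobial polymers that mimic host-defense peptides bind bacterial
membranes through a combination of electrostatics, hydrophobic insertion
and — when the side chain carries an amide rather than its isosteric
ester — hydrogen bonding to lipid head groups. Testing that mechanism
quantitatively requires the same small set of analyses over and over:
counting geometric hydrogen bonds in simulation snapshots, measuring
lipid reorganization around the polymer, decomposing nonbonded
interaction energies, fitting calorimetric titrations, and tracking
vibrational-mode shifts in Raman spectra. `memint` packages those
analyses as a tested, reusable library with a synthetic-data module that
generates every input with planted ground truth, so each method can be
validated against an exact oracle before it touches real data.

## What it computes

**Hydrogen bonds** (`memint.hbond_analysis`) — geometric criterion:
donor–acceptor distance ≤ 4.0 Å and deviation of the D–H···A angle from
linearity ≤ 60° (∠D–H–A ≥ 120°), minimum-image distances, inclusive
boundaries. Per-frame counts, block-averaged errors, breakdown by
donor/acceptor chemistry and lipid species, participating side arms.

**Membrane organization** (`memint.membrane_organization`) — leaflet
assignment from phosphate z; radial distribution functions

g(r) = ⟨n_B(r, r+dr)⟩ / (N_A · ρ_B · 4πr²dr)

with periodic boundaries; 2-D lateral number densities per leaflet with
Pearson colocalization; polymer conformation metrics (R_g, end-to-end
distance, in-plane extent, head-group contacts) and detection of side
arms sequestered past the phosphate plane.

**Interaction energetics** (`memint.interaction_energetics`) — pairwise
electrostatic (C·q_iq_j/r, C = 332.0636 kcal·Å/(mol·e²)) and
Lennard-Jones (ε_ij[(R_min/r)¹² − 2(R_min/r)⁶], CHARMM combination
rules) sums with a cubic switching function on 10–12 Å, normalized per
sequestered side arm.

**Binding thermodynamics** (`memint.binding_thermo`) — the one-set-of-
sites calorimetric isotherm (Wiseman model with perfusion-cell dilution
bookkeeping), nonlinear least-squares fit of (n, K_a, ΔH), and the
mole-fraction standard-state identity

ΔG = −RT ln(55.5 K_a) = ΔH − TΔS,  R = 1.986 cal mol⁻¹ K⁻¹,

plus Laurdan generalized polarization GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀).

**Vibrational spectra** (`memint.vibrational_spectra`) — polynomial
baseline correction with iterative peak clipping, sum-of-Lorentzians
fitting, mode-softening quantification (Δν < 0), PO₂⁻ doublet-splitting
detection by corrected information criterion with physical
resolvability gates, and temperature-series band-emergence analysis
(e.g. the amide-I band near 1680 cm⁻¹ appearing when a polymer–lipid
hydrogen bond melts).

**Synthetic systems** (`memint.synthetic_systems`) — coarse-bead
bilayer patches (default 90 PE-like + 38 PG-like lipids, four
12-monomer polymer chains placed 12–18 Å above the upper leaflet) with
exactly k planted hydrogen bonds, planted lipid-density clusters,
controllable side-arm insertion, one-site ITC isotherms, two-band
emission spectra and multi-Lorentzian Raman spectra — all
seed-deterministic, with ground truth returned alongside.

## Worked example

```python
from memint.synthetic_systems import BilayerSpec, build_system, plant_hbonds, simulate_itc
from memint.hbond_analysis import summarize_hbonds
from memint.molecular_model import Trajectory
from memint.binding_thermo import fit_one_site

system = build_system(BilayerSpec(polymer_kind="amide", seed=7))
frame, truth = plant_hbonds(system, k=7, seed=8)
summary = summarize_hbonds(Trajectory(system.topology, [frame]))
print(f"hydrogen bonds per frame: {summary.mean_per_frame:.1f}")
print(summary.counts_by_pairing)

isotherm = simulate_itc(Ka_per_M=1e6, dH_kcal_per_mol=2.5, noise_sd_ucal=0.05, seed=7)
params = fit_one_site(isotherm)
print(f"n = {params.n_sites:.3f}, Ka = {params.Ka_per_M:.3e} 1/M")
print(f"dH = {params.dH_kcal_per_mol:.3f} kcal/mol, dG = {params.dG_kcal_per_mol:.2f} kcal/mol")
```

prints

```
hydrogen bonds per frame: 7.0
                                          mean_per_frame
donor_group acceptor_group lipid_species
amide N-H   phosphate O    POPE                      7.0
n = 1.001, Ka = 1.025e+06 1/M
dH = 2.492 kcal/mol, dG = -11.00 kcal/mol
```

The detector recovers exactly the seven planted amide-N–H → phosphate-O
bonds, and the calorimetric fit inverts the simulated titration (true
K_a = 10⁶ M⁻¹, ΔH = 2.5 kcal/mol) to within the injected noise; ΔG is
reported on the 55.5 M water standard state. An entropy-driven binder —
positive ΔH, strongly negative ΔG — is the signature of hydrophobically
driven membrane insertion.

A configurable end-to-end run over synthetic amide/ester/hexyl systems:

```bash
memint run --config demo.yaml --seed 1 --outdir out/
```

(any block of the YAML config — `md`, `itc`, `gp`, `raman` — may be
omitted to skip that stage; see `memint.pipeline.PipelineConfig` for
all knobs). Per-stage subcommands exist too: `memint hbonds`, `memint
rdf`, `memint energy`, `memint itc-fit`, `memint gp`, `memint
raman-peaks`, `memint raman-split`, `memint raman-tseries`.

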