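# epistat

Analysis toolkit for **electrostatic complementarity at antigen–antibody
interfaces**: crystal-contact geometry, molecular-dynamics stability metrics,
per-residue interaction-energy decomposition, and SPR binding
kinetics/thermodynamics — with seeded synthetic-data generators so every
stage runs and is testable without wet-lab data or cluster-scale simulations.

The motivating system is the complex between the neutralizing antibody A6 and
the interferon-γ receptor (IFNγR), whose interface is stabilized by a small
set of salt bridges (antigen K52 against heavy-chain D54/D56, antigen R84
against light-chain E27, antigen K98 against light-chain D28). Swapping the
charges on both sides of such a pair ("charge exchange", e.g. Ag:R84E with
V_L:E27R) can restore binding that either single charge inversion abolishes;
this package implements the quantitative analyses used to characterize that
behaviour.

## What it computes

**Interface geometry** (`epistat.structures`). PDB parsing into light-weight
models, then charged-group distances in two conventions, both always
reported: the *representative-atom* distance (Lys NZ, Arg CZ, Asp CG, Glu
CD) and the *group-minimum* distance (closest approach of
ammonium/guanidinium N to carboxylate O). `find_salt_bridges` scans two chain
selections for (basic, acidic) pairs within a cutoff.

**Trajectory stability metrics** (`epistat.trajectory`). Kabsch (SVD)
superposition with reflection exclusion; Cα RMSD against a reference
structure; **ligand-RMSD (L-RMSD)** — the RMSD of the antibody Cα atoms after
superposing only the antigen Cα atoms, a direct readout of whether a complex
keeps its binding pose; per-frame contact distance series; **occupancy**, the
fraction of post-burn-in frames with a contact distance at or below its
threshold (default: the contact's own crystal-structure distance); and
replica aggregation (mean, sample sd, standard error).

**Interaction energies** (`epistat.energetics`). Per-residue decomposition of
the interaction with partner chains into Coulomb `f·q₁q₂/(ε·r)`
(f = 1389.35458 kJ·Å·mol⁻¹·e⁻²) and 12-6 Lennard-Jones
`4ε[(σ/r)¹² − (σ/r)⁶]` terms with Lorentz–Berthelot combining, truncated at
12 Å, time-averaged per replica and aggregated with a standard error.
Parameters come from a user-supplied per-atom table, never from a built-in
force field.

**Binding kinetics and thermodynamics** (`epistat.binding_kinetics`). 1:1
Langmuir sensorgram simulation and **global** nonlinear fitting of
(k_on, k_off, R_max) across a concentration panel with K_D = k_off/k_on;
van't Hoff regression `ln K_D = ΔH/RT − ΔS/R`; ΔG = ΔH − TΔS with full
covariance error propagation; and DSC apparent melting temperature (T_m,app)
as the temperature of maximum heat capacity.

**Synthetic data** (`epistat.synthetic_data`). Toy complexes with planted
contacts at exact distances, trajectories with exact-by-construction
occupancies and optional dissociation drift, sensorgram panels at the
standard six two-fold dilutions (1000 → 31.25 nM), KD(T) series, and
thermograms — each a pure function of its seed, returning ground truth for
recovery tests.

**Pipeline** (`epistat.pipeline`, `epistat` CLI). YAML-configured end-to-end
runs producing provenance-tagged CSV tables, JSON summaries and a log.

## Worked example

```python
from epistat import (fit_kinetics_global, make_interface_standin,
                     make_sensorgram_panel, representative_distance,
                     group_min_distance, vant_hoff_fit, make_kd_series,
                     delta_g_propagated)

# interface geometry, both conventions (synthetic stand-in of the
# IFNgR-A6 interface with the published contact distances planted)
model = make_interface_standin()
k52, d54 = model.find_residue("I", 52), model.find_residue("H", 54)
print(f"K52-D54  NZ-CG: {representative_distance(model, k52, d54):.1f} A, "
      f"NZ-carboxyl-O minimum: {group_min_distance(model, k52, d54):.1f} A")

# simulate a six-dilution SPR panel at the wild-type rates + 1% noise, refit
panel = make_sensorgram_panel(kon=2.7e5, koff=2.3e-2, rmax=100.0,
                              noise_sd=1.0, seed=42)
fit = fit_kinetics_global(panel)
print(f"fitted kon = {fit.kon:.2e} /M/s, koff = {fit.koff:.2e} /s, "
      f"KD = {fit.kd*1e9:.0f} nM")

# van't Hoff round trip and propagated binding free energy
vh = vant_hoff_fit(make_kd_series(dh=-50.0, ds=-0.03))
dg, dg_sd = delta_g_propagated(vh, 298.0)
print(f"dH = {vh.dh:.1f} kJ/mol, dS = {vh.ds*1e3:.1f} J/mol/K, "
      f"dG(298 K) = {dg:.2f} kJ/mol")
```

Output:

```
K52-D54  NZ-CG: 3.6 A, NZ-carboxyl-O minimum: 2.8 A
fitted kon = 2.70e+05 /M/s, koff = 2.31e-02 /s, KD = 86 nM
dH = -50.0 kJ/mol, dS = -30.0 J/mol/K, dG(298 K) = -41.06 kJ/mol
```

The geometry line shows the two distance conventions on the wild-type
K52–D54 hot-spot contact; the kinetics line shows that a noisy six-curve
panel refits to the generating rates (K_D ≈ 86 nM vs. the 85 nM implied by
the input rates); the last line shows exact van't Hoff recovery and the
resulting binding free energy.

A shell session does the same through the CLI:

```sh
epistat spr-simulate --kon 2.7e5 --koff 2.3e-2 --noise 1 --seed 42 --out panel.csv
epistat spr-fit panel.csv
epistat run config.yaml        # full pipeline from a YAML config
```

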