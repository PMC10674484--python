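# lipoagg

Quantitative analysis of lipopeptide self-assembly from fluorescence and
coordinate data. The package targets the workflow used to characterise
aggregating therapeutic lipopeptides (peptides carrying a fatty-acid chain,
such as GLP-1 analogues): time-resolved fluorescence gives the probe's
lifetime, steady-state anisotropy gives the tumbling time and hence a
hydrodynamic size, a pyrene titration locates the critical aggregation
concentration (cac), and simulation or NMR coordinate models give the
matching geometric descriptors.

## What it computes

**TCSPC decay fitting** (`lipoagg.decay`). Photon-count histograms are fit
with a sum of exponentials under Poisson weighting (variance `max(counts, 1)`),
by tail fitting from the count maximum or by reconvolution with a measured
instrument response. The amplitude-weighted mean lifetime
⟨τ⟩ = Σᵢ αᵢ τᵢ summarises a multi-component decay.

**Anisotropy hydrodynamics** (`lipoagg.hydrodynamics`). For a globular
particle, the Perrin equation for a spherical rotor,
r₀/r = 1 + τ/σ, converts steady-state anisotropy `r` (with limit anisotropy
`r₀` and lifetime `τ`) into the rotational correlation time σ, and the
Stokes–Einstein–Debye relation Vₕ = σRT/(ηN_A) converts σ into a
per-molecule hydrodynamic volume; a sphere of that volume defines Rₕ.

**cac estimation** (`lipoagg.cac`). Pyrene's I₁/I₃ vibronic ratio
(372 nm / 387 nm band maxima) is extracted from emission spectra and fitted
against log₁₀(concentration) with two straight lines; the cac is the
intersection of the near-flat polar branch and the steeply descending
apolar branch. The breakpoint is found by an exhaustive scan over splits of
the sorted points (≥ 3 points per side), with a bootstrap confidence
interval.

**Structure metrics** (`lipoagg.structure`). From PDB coordinates
(multi-MODEL files are read as trajectory frames): mass-weighted radius of
gyration, the Kirkwood hydrodynamic radius Rₕ = ⟨r_ij⁻¹⟩⁻¹ over carbon
atoms, sphere volumes from either radius, and per-residue Cα RMSF with
optional rigid-body superposition.

**Synthetic data** (`lipoagg.synthetic`). Seeded generators for every input:
Poisson-noise multi-exponential decays (optionally convolved with a Gaussian
IRF), polarized intensity pairs, piecewise-linear pyrene titrations, and
geometry fixtures (helices, uniform balls) with closed-form reference values.

## Worked example

```python
from lipoagg import (DecaySimSpec, HydroConditions, generate_decay,
                     fit_multiexponential, hydro_chain)

# simulate a tryptophan-like decay (50 ns window, 1024 channels,
# lifetimes 1.22/3.66/7.40 ns with weights 0.45/0.41/0.14) and refit it
trace = generate_decay(DecaySimSpec(seed=7))
fit = fit_multiexponential(trace, n_components=3, reconvolve=True)
print(f"<tau> = {fit.average_lifetime_ns:.2f} ns")

# steady-state anisotropy 0.110 in water at 298 K -> hydrodynamic size
cond = HydroConditions(viscosity_cP=0.89, temperature_K=298.0, r0=0.260)
h = hydro_chain(r=0.110, tau_ns=3.0, cond=cond)
print(f"sigma = {h.sigma_ns:.1f} ns, Vh = {h.Vh_nm3:.1f} nm^3, "
      f"Rh = {h.Rh_A:.1f} A")
```

prints

```
<tau> = 3.07 ns
sigma = 2.2 ns, Vh = 10.2 nm^3, Rh = 13.4 A
```

⟨τ⟩ is the amplitude-weighted mean of the three fitted lifetimes (the truth
gives 3.09 ns; a single noisy trace scatters around it). The anisotropy
chain says a particle tumbling with σ = 2.2 ns in water at 298 K occupies
about 10.2 nm³ — a hydrodynamic radius of 13.4 Å, i.e. a small oligomer
rather than a monomeric peptide.

The same stages run from the shell:

```sh
lipoagg simulate --kind titration --out titr.tsv --seed 1
lipoagg cac --table titr.tsv --out-json cac.json
lipoagg report --config run.yaml     # multi-stage run from a YAML config
```

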