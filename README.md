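# gnplem

Modelling and statistics for gold-nanoparticle (GNP) radiosensitization of
MDA-MB-231 breast-cancer cells under clinical 6 MV photon irradiation, alone
and combined with cisplatin chemoradiation.

The package is aimed at radiation biophysicists who want to reproduce, on a
desk machine, the chain of reasoning in a GNP chemoradiation study: how many
particles cells internalize, how much extra physical dose those particles
deliver to the nucleus, how that translates into predicted survival, and how
the measured clonogenic and DNA-damage statistics compare.

## The model

**Clonogenic statistics.** Plating efficiency PE = colonies / cells plated on
control dishes; survival fraction SF = colonies / (cells plated × PE).
Sensitization is reported as the percent decrease 100 × (1 − SF_arm/SF_ref)
with a first-order delta-method error.

**GNP-LEM dosimetry.** A single irradiated GNP deposits excess dose in a
radial kernel k(r) around itself. The package generates a calibrated power-law
stand-in, k(r) ∝ r^−2 binned out to r_max = 5 µm, normalized so the
shell-integrated excess energy per GNP per Gy equals η · m_Au · 1 Gy
(η = 0.5 by default; total kernel energy therefore scales with diameter³);
externally computed kernel tables can be supplied instead. The cell is an
ellipsoid (semi-axes 7.75 × 5.75 × 5.75 µm) with a 4 µm-radius spherical
nucleus; 367,000 GNPs are placed uniformly in the cytoplasm, perinuclearly
(acceptance ∝ exp(−d/1 µm) in distance d from the nucleus surface), or inside
500 nm vesicles of 100 GNPs. The nucleus dose field is sampled at Monte-Carlo
integration points, d_i = D(1 + Σ_g k(‖p_i − x_g‖)), and the local effect
model converts it to survival: N = ⟨αd + βd²⟩, SF = exp(−N), with
α = 0.002 Gy⁻¹, β = 0.079 Gy⁻² at D = 2 Gy.

**Combination and fractionation.** Bliss independence predicts the
combination survival as the product of the single-modality SFs; an observed
SF within 2 SEM of the product is called additive. Tumor control assumes
Poisson statistics: after n identical fractions, survivors = N₀ · SFⁿ and
TCP = exp(−survivors).

**Synthetic data.** Because no raw data are deposited, a seeded generator
emulates every measured table: binomial colony counts, lognormal per-cell
gold masses, Poisson 53BP1 foci over lognormal nuclear areas, and the TEM
diameter sample. Every estimator is tested by recovering the generating
parameters.

## Worked example

```python
from gnplem.lem import run_scenario
df = run_scenario("perinuclear", 367_000, 10.0, seeds=(0, 1, 2))
print(df[["seed", "sf_bg", "sf_gnp", "reduction_pct"]])
```

```
   seed     sf_bg    sf_gnp  reduction_pct
0     0  0.726149  0.725603       0.075227
1     1  0.726149  0.725606       0.074888
2     2  0.726149  0.725603       0.075196
```

The no-GNP baseline is the LQ closed form exp(−(0.002·2 + 0.079·4)) = 0.7261;
367,000 perinuclear 10 nm GNPs lower predicted survival by ≈ 0.075%. Running
all scenarios (`analysis/04_lem_dosimetry.py`) prints:

```
  10 nm  uniform_cytoplasm   SF reduction 0.0506%
  10 nm  perinuclear         SF reduction 0.0751%
  10 nm  vesicle             SF reduction 0.0495%
   2 nm  perinuclear         SF reduction 0.0006%
```

Perinuclear placement gives the largest physical effect, uniform and
vesicle-confined placements are equal within Monte-Carlo scatter, and 2 nm
particles at the same number are weaker by the 1/125 gold-mass ratio — all
well below the ~19% sensitization measured biologically, showing that
physical dose enhancement alone cannot account for the observed effect.

The numbered scripts under `analysis/` walk the full study: construct
characterization and uptake (01), clonogenic survival and sensitization
contrasts (02), 53BP1 foci densities (03), LEM dosimetry (04), Bliss
combination call and TCP fractionation (05). Each writes its table under
`results/`.

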