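# Methods

## Scope and structure

`gnplem` links the physical and biological halves of a GNP radiosensitization
experiment: particle uptake arithmetic, nucleus dosimetry by radial-kernel
superposition, local-effect-model (LEM) survival prediction, clonogenic and
DNA-damage statistics, Bliss combination analysis, and Poisson tumor-control
arithmetic. Particle transport itself (track-structure Monte Carlo) is out of
scope; its product — the per-GNP radial excess-dose kernel — is the package's
input boundary, either generated parametrically or read from a TSV table.

## Radial dose kernel

A kernel tabulates excess dose per GNP per Gy of prescribed dose in
spherical shells from the particle surface to a range `r_max`. The generated
stand-in is a power law k(r) ∝ r^−exponent with defaults:

| parameter | default | meaning |
|---|---|---|
| `eta` | 0.5 | dimensionless excess-absorption factor; kernel's total energy is η·m_Au·1 Gy |
| `exponent` | 2.0 | far-field falloff typical of secondary-electron dose around a point source |
| `r_max_um` | 5.0 µm | kernel range; reaches the nucleus from any cytoplasmic position |
| `n_bins` | 2048 | radial shells, uniform in r² |

η folds the spectrum-averaged excess mass-energy absorption of gold over
water for a 6 MV beam at 10 cm depth (including the scattered low-energy
component) into a single calibration constant; no published normalization
exists for this geometry, so η is exposed in configuration rather than
hard-coded. Calibration is exact by construction: the power law is rescaled
so the shell-mass-weighted energy sum equals the target, which also makes
total kernel energy scale exactly as diameter³ (the 2 nm / 10 nm energy
ratio is 1/125).

Bin edges are uniform in r², which lets the superposition map a squared
distance to its shell with a single multiply (no square root, no search) —
this is what makes 367,000-particle runs take seconds rather than minutes on
one core. The cost is coarser radial resolution near the particle surface;
with 2048 bins the first shell spans ~5–110 nm and carries ~2% of the
kernel's energy, negligible at cell scale. Dose queries below the first edge
return the first shell's value; at or beyond `r_max`, exactly zero.

## Cell geometry and GNP placement

The cell is an axis-aligned ellipsoid, semi-axes 7.75 × 5.75 × 5.75 µm
(elliptical diameters 15.5 × 11.5 µm; the unstated third axis defaults to
the minor one and is configurable), with a centred spherical nucleus of
radius 4 µm. GNPs never enter the nucleus.

* **uniform_cytoplasm** — rejection sampling: uniform in the ellipsoid,
  nucleus interior rejected.
* **perinuclear** — uniform proposals accepted with probability
  exp(−d/λ), d the distance to the nucleus *surface* (the alternative —
  distance to the centre — would only shift the normalization); decay length
  λ defaults to 1 µm, a value that concentrates most particles within the
  first couple of microns of the nuclear envelope as perinuclear clustering
  micrographs show.
* **vesicle** — ceil(n/100) vesicles of 500 nm diameter, centres uniform in
  the cytoplasm with the whole vesicle inside it, each filled with 100 GNPs
  uniform in its sphere (the last takes the remainder).

Vesicle centres may overlap by default. At the study scale (3670 vesicles)
the required centre density is ≈99.5% of the hard-sphere random-sequential-
addition saturation limit, so strict non-overlap is unattainable by dart
throwing; since overlapping vesicles merely cluster GNPs slightly more — a
negligible perturbation next to the vesicle-vs-individual contrast itself —
overlap is accepted. A `min_center_separation_um` option restores strict
dart-throwing (with a retry budget and an advisory error) for smaller
problems. The rare vesicle-interior draw that would cross the cell boundary
is redrawn inside its vesicle, so every emitted coordinate satisfies the
cytoplasm predicate exactly.

All samplers are pure functions of (geometry, config, seed) via
`numpy.random.default_rng`; identical inputs give bit-identical placements.

## Nucleus dosimetry and LEM survival

Nucleus dose is evaluated at Monte-Carlo integration points uniform in the
nucleus sphere (default 10,000) rather than a voxel grid — with 367,000
sources and a smooth kernel the spatial mean converges quickly, and seed
scatter of the resulting survival reduction is ≈0.3% relative. Each point
receives d_i = D(1 + Σ_g k(‖p_i − x_g‖)) with D = 2 Gy uniform background
(macroscopic beam structure is out of scope). The production path restricts
pairs to the kernel cutoff and is compiled with numba; a pure-numpy
all-pairs oracle with identical bin semantics is kept as an independent
cross-check and agrees to float roundoff (tested at 1e-12 relative).

The LEM converts the field to survival: lethal-event density
N = mean(α d + β d²), SF = exp(−N), α = 0.002 Gy⁻¹ and β = 0.079 Gy⁻² for
MDA-MB-231 at 6 MV. For a uniform field this is the LQ closed form
(SF(2 Gy) = exp(−0.32) = 0.7261); for heterogeneous fields with the same
mean it predicts lower survival (Jensen's inequality, β > 0). Note these LQ
parameters imply a 2 Gy baseline survival of ≈0.73 while the measured
irradiated-control SF is ≈0.31; the two scales are not reconciled here, and
only *relative* reductions are reported, as is standard for this model
class. Reported reductions average three seeds per scenario and the maximum
across scenarios is the headline physical-dose effect.

## Assay statistics

Plating efficiency pools colonies over control plates (the defining formula
acts on counts, so pooling rather than per-plate averaging is the faithful
reading). Survival estimates are mean ± SEM over replicates; an estimate may
exceed 1 by sampling noise on a non-toxic arm, so validation rejects only
mean < 0 or mean > 1 + 3·SEM. Percent-decrease errors use the first-order
delta method on the ratio of two independent means — the propagation rule
behind the study's printed ±6% is unstated, and the delta method gives ±5.0
and ±4.5 for the two contrasts, consistent with the printed rounding. Foci
density pools counts over total projected area with a per-nucleus SEM.
Pairwise significance uses Welch's unequal-variance t-test
(`scipy.stats.ttest_ind`), cross-checked against a permutation test.
ANOVA with multiple-comparison correction is deliberately not exposed.

## Synthetic data generator

The generator emulates the statistical structure of each measured table at
the study's own design points:

* colony counts ~ Binomial(cells plated, PE × SF) with nine plates per arm,
  PE 0.5 and 1000 cells per plate (PE and plating are unstated in the
  source; 0.5 and 1000 are typical clonogenic practice and give colony
  counts in the countable range), true SFs {1.0, 1.0, 0.61, 0.60, 0.31,
  0.25, 0.23, 0.16} across the eight arms. An overdispersion hook is absent
  by design — binomial is the minimal mechanism consistent with the PE/SF
  definitions, and the recovery tests quantify exactly that idealization.
* per-cell gold masses lognormal around count × particle mass at the CVs
  implied by the printed uptake spreads (2.1%, 13.1%, 1.8%); whether those
  are SDs or SEMs is unstated, so both interpretations are selectable
  (`spread="sd"` default).
* foci counts ~ Poisson(density × area) with lognormal projected areas
  (median 150 µm², log-sd 0.35 — a plausible adherent-nucleus distribution;
  the source gives none) at densities {0.024, 0.026, 0.026, 0.040}/µm² and
  the reported nucleus counts {274, 310, 307, 357}.
* TEM diameters normal (10.04, 0.89) nm truncated at zero, n = 50.

What passing recovery tests show: the estimators are unbiased and correctly
scaled against these mechanisms. What they do not show: robustness to real
plate-to-plate overdispersion, segmentation errors in foci counting, or
ICP-AES calibration drift — none of which the generator models.

## Numerical and testing choices

Distances are µm at cell scale and nm inside kernels; the kernel layer owns
the conversion. Recovery assertions at 2 SEM are ~95% statements, so
stochastic recovery checks with wide CVs assert coverage over ten seeds
rather than a single draw. Study-scale dosimetry checks (367,000 GNPs,
10⁴ points, three seeds, both diameters) run in ~2.5 minutes on one core
and are shared across tests through a session fixture.

## Known limitations

* The power-law kernel is a calibrated stand-in, not a track-structure
  result; absolute reduction magnitudes inherit η's uncertainty, while
  scenario orderings and size scalings are insensitive to it.
* No repair kinetics, cell-cycle structure, oxygen effect, or chemical
  (radical-mediated) pathway — the known gap between physical-dose LEM
  predictions (≲0.1%) and measured sensitization (~19%).
* The Poisson TCP ignores interpatient heterogeneity and repopulation; it
  is a proof-of-principle fractionation argument only.
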