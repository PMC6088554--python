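# Methods

## Scope and overall design

`abfret` models one system: the Aβ 12–28 fragment, capped and extended by a
cysteine at each terminus (fragment numbering 11–29, hydrophobic core
L17–A21), with a cationic dye grafted to each terminal cysteine. The package
connects conformational ensembles of this construct, for peptide charge
states 3+–6+ (1–4 mobile protons plus the two fixed chromophore charges), to
the two observables that characterise it in the gas phase — collision cross
section and FRET efficiency — and to Ramachandran structural families of the
core. All-atom molecular dynamics is deliberately out of scope: the
conformer model is a coarse dihedral-space surrogate built to express one
physical driver, the competition between intrinsic secondary-structure
preferences and inter-charge Coulomb repulsion, at desk scale and fully
seeded.

## Conformer model

**Geometry.** Residues are built with ideal backbone internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; τ(N-CA-C) 111.2°, ω fixed trans)
by NeRF chain extension from per-residue (φ, ψ). Each non-glycine residue
carries one side-chain pseudo-atom (CB). Each chromophore is a rigid planar
7-atom token (≈ 5 Å long axis, standing in for a xanthene-like dye core)
attached to the terminal cysteine CB through a 3 Å linker pseudo-atom with
two free torsions, representing the flexibility of the real C5 linkers. The
token declares one charge atom (X4) and a long-axis dipole pair (X1, X5).
The "optical unit" of each dye is the 7 token atoms; its centre is their
unweighted geometric mean.

**Energy.** Dimensionless, in units of kT at 300 K; temperature enters only
through ratios. Terms and shipped defaults:

| term | form | default |
|---|---|---|
| torsional basins | −Σ depth·exp(−(Δφ²+Δψ²)/2w²), wrapped | α(−63,−43) 3.1 kT; β(−135,135) 1.2 kT; PPII(−75,145) 0.9 kT; w = 25° |
| run cooperativity | −coop per consecutive pair inside a basin's ±40° membership box | α 1.8, β 1.8, PPII 1.8 kT |
| Coulomb | +k·q_iq_j/r over charge sites | k = 115 kT·Å |
| tertiary contacts | −depth·exp(−(r−r₀)²/2w²) over hydrophobic CB pairs, \|Δres\| ≥ 5 | 3.2 kT at 6.2 ± 2.0 Å |
| soft spheres | +k_ss(σ−r)² for r < σ, \|Δres\| ≥ 2 | σ 3.2 Å, k_ss 10 kT/Å² |
| proline φ restraint | quadratic outside [−90°, −50°] | 0.03 kT/deg² |

Two sequence-specific rules implement the F19P contrast: proline has no
α-basin well and a restrained φ; and proline is treated as a *strand
breaker* — the β well and β-run membership are removed for proline and both
flanking residues, standing in for the missing backbone NH (no β H-bond
ladder through a proline) and the ring's constraint on the preceding
residue. Without the neighbourhood rule the mutant shows *more* core β than
WT at 6+ (removing the α well locally just frees those residues to convert),
inverting the observed contrast.

**Why these numbers.** The basin depths were balanced against the *sampled*
free energies, not the well minima: extended basins carry far more
conformational entropy (no steric frustration), so equal cooperativities
across basins plus a deeper α well reproduce a helix-dominant neutral chain.
The Coulomb prefactor is an effective value: the literal vacuum constant
(≈ 561 kT·Å) would flatten every charge state into maximally extended chains,
because the few-kT torsion wells lack the tens of kT of backbone H-bond
cohesion that oppose Coulomb repulsion in the real system. k = 115 kT·Å was
chosen from a static analysis of the helix/extended Coulomb differential per
charge state (0.02k at 4+, 0.17k at 5+, 0.23k at 6+) so that the
helix→extended flip lands between 5+ and 6+, with the ≈ 0.17k helix premium
supplied by the basin/cooperativity balance. The tertiary contact term (only
\|Δres\| ≥ 5 pairs, so a helix cannot satisfy it with its own i, i+3/i+4
geometry) makes the weakly charged 3+ state a compact globular coil. Protons
are placed on the basic side chains (H13, H14, K16, K28) by minimum Coulomb
energy on the idealised helical build, enumerated over all subsets; an
explicit `ProtonationState` overrides this.

**Sampling.** Replica-exchange Metropolis Monte Carlo over the geometric
ladder T_k = 220·(850/220)^(k/19) K (20 rungs; the closed form reproduces
all twenty conventional rung temperatures after rounding). One step attempts
one move in every replica: a single-residue (φ, ψ) pivot (Gaussian step of
25°, 30% chance of a uniform jump) or, with 15% probability, one chromophore
linker torsion. Adjacent-pair exchanges use the standard criterion
min(1, exp[(β_i−β_j)(E_i−E_j)]) every 200 steps; equal temperatures always
exchange. Pivot moves update coordinates incrementally (rigid rotation of
the downstream block), and a property test confirms the incremental and
fully rebuilt energies agree. The production ensembles are read from the
292 K rung (rung 4), the temperature at which the structural-family analysis
is most informative; `sample_ensemble` defaults to the coldest rung.
Production runs use 24 000 steps, 4 000 burn-in, stride 100 → 200 structures,
≈ 10 s per ensemble on one core (the pairwise-energy and rotation inner
loops are numba kernels).

**Exchange acceptance.** For the shipped defaults the ladder-mean swap
acceptance is ≈ 0.8 and no pair stalls; the hottest pairs saturate near 1
because, for a 17-residue system, adjacent hot rungs have almost completely
overlapping energy distributions. The property test therefore bounds the
ladder mean inside (0.05, 0.95) and every pair above 0.05, rather than
asserting the upper bound per pair.

## Collision cross sections

PA: Monte Carlo shadow area — uniform random orientations (quaternion
method), points sampled in the bounding disc of the projected collision
circles, Ω = A·hit-fraction averaged over orientations. EHSS: per
orientation, hard-sphere trajectories start on the same disc and propagate
along +z; at each encounter the trajectory reflects specularly off the first
intersected sphere (ties broken by atom index; 100-reflection cap with an
exposed counter; trajectories starting inside a sphere are discarded and
counted); each trajectory contributes (1 − cos χ) with χ the total
deflection, so Ω is the momentum-transfer cross section. EHSS = PA on convex
bodies and exceeds it on re-entrant ones. Collision radii are pre-combined
with He (H 2.2, C/N/O 2.7, S 3.1, pseudo-atoms 2.7 Å) and fully
overridable; no radius value is load-bearing for any test — all assertions
are internal-consistency (analytic sphere, scale law, EHSS ≥ PA, invariance).
Defaults are 500 orientations × 2000 trajectories with the standard error
over orientations always reported; ensemble batches in the study use
32 × 150 (per-conformer SE ≈ 2–3%, small against the ensemble spread).
Ensemble means are unweighted over sampled structures (the sampler already
draws from the Boltzmann distribution at the analysis temperature); an
optional weight vector is not provided because no test or output needs one.

## FRET

R is the distance between optical-unit centres; κ² comes from the declared
dipole axes; E = R₀eff⁶/(R₀eff⁶+R⁶) with R₀eff⁶ = R₀⁶κ²/(2/3). The shipped
R₀ = 49 Å is an uncalibrated placeholder — no spectral-overlap calculation is
performed, and every quantitative statement in tests and outputs is relative
to R₀. Per-conformer efficiencies are averaged ("static" regime); the
fast-orientation alternative (averaging the rate-like R₀eff⁶/R⁶ first) is
available as `averaging="dynamic"`. κ² is explicit per structure by default,
with an isotropic-2/3 mode as option; the explicit mode is the default
because the chromophore orientation distribution is exactly what the
conformer model resolves. Conformers with R < 15 Å are flagged (short-range
Dexter transfer invalidates the point-dipole picture there); they are
flagged, never modelled.

## Action-FRET reduction

Fragmentation yield = (acceptor-specific fragment intensity / total ion
current) ÷ photon flux, with flux ∝ pulse energy × wavelength (the
proportionality constant cancels in the ratio). This simple fraction, rather
than −ln(1−f), is adequate at the low single-pulse yields generated and is
recorded in the output metadata. Yields are averaged over the five repeats
per wavelength; the acceptor direct-excitation correction (0.25) is
subtracted from the ratio of means, i.e. after averaging, and that order is
recorded in the result object. Negative corrected efficiencies are reported
with a warning, never clipped. Acceptor fragments are matched from a
user-supplied m/z list at ±0.3 Th.

## Ion-mobility reduction

Centroid (intensity-weighted mean) arrival times — robust on sparse
synthetic histograms; a Gaussian-apex option is deliberately not shipped —
are regressed on 1/V by OLS; slope = L²/K, intercept = t₀; R² and parameter
standard errors always reported. CCS follows Mason–Schamp with all constants
from `scipy.constants` and all unit conversions centralised in one module
(mobility implementations disagree most often through unit slips). A
multi-modal ATD raises a warning (two local maxima above 30% of the peak
separated by a valley below 40% of the smaller) and still returns the global
centroid; deconvolution is out of scope.

## Synthetic instrument

Spectra: the 545 nm fragment fraction is a·flux and the 505 nm fraction
a·(E*+0.25)·flux, so the flux-normalised yield ratio is E*+0.25 in
expectation and the reduction recovers E* exactly up to Poisson noise;
counts are Poisson with the declared budget, pulse energies uniform on
1.0–4.5 mJ, three fixed fragment channels. ATDs: K from the inverse
Mason–Schamp at the measurement conditions, t = L²/(KV)+t₀, and 50 ion
arrivals per voltage each jittered by the noise fraction — an arrival-time
*distribution*, so the centroid noise shrinks as 1/√50.

## What the synthetic data do and do not show

The generators emulate: charge-state-driven structural change with its
correct observable signatures (CCS up, FRET down with charge; helix loss
from 4+ to 6+; a core β signature in WT 6+ absent in F19P 6+; a compact
coil at 3+), Poisson counting statistics, pulse-energy variation, and drift
time linearity in 1/V. They do not emulate: real force-field energetics or
absolute CCS/FRET values (the toy ensembles are not quantitative — no
comparison against experimental per-charge-state numbers is attempted),
isotope envelopes, detector saturation, multi-conformer ATD structure, or
solution-phase chemistry. Passing tests therefore demonstrate correctness of
the observable computations and reductions, and the qualitative fidelity of
the charge-state narrative — not quantitative agreement with any experiment.

## Numerical choices and degenerate inputs

Angles wrap on (−180°, 180°]; toroidal distances are Chebyshev (max of
per-angle wrapped differences), boundary-inclusive in the overlap score.
Region rectangles (α φ∈[−100,−30] ψ∈[−67,−7]; β φ∈[−180,−90] ψ∈[90,180];
PPII φ∈[−90,−55] ψ∈[120,180]; left-α φ∈[30,100] ψ∈[7,67]) are ordered,
first match wins, with β declared before PPII; the map is config data and
round-trips through YAML. Zero-length dipole axes, coincident charges,
empty selections, empty ensembles, non-positive mobilities and unsorted
ladders are errors, not silent fallbacks. Insertion codes are rejected;
first altloc wins. PDB round trips preserve coordinates to the format's
3-decimal precision. The packaged reference dihedral sets (helical
solution-monomer core, β fibril core) are synthetic stand-ins generated
programmatically and labelled as such in their filenames and headers; the
overlap statistic against them is this package's own quantification of an
otherwise visual comparison.

## Known limitations

The conformer model is a cartoon: no H-bonds, no ω flexibility, no
side-chain rotamers beyond one pseudo-atom, an effective Coulomb prefactor,
and a strand-breaker rule standing in for real β-sheet physics. Proton
placement by centroid Coulomb enumeration prefers H13/K28 at two protons
where all-atom energetics select K16/K28; the difference does not affect any
shipped trend. The 5+ state unfolds somewhat more than a "distorted helix".
EHSS uses hard spheres only (no long-range He–atom potential), so absolute
cross sections carry the usual hard-sphere bias. The mobility fit assumes a
single conformer family; multimodal ATDs are flagged, not resolved.
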