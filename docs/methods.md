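# Methods

This note documents the models implemented in `hostguest`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter when comparing results.

## Phase solubility and stability constants

**Model.** A 1:1 host–guest equilibrium `G + H ⇌ GH` with an excess of
solid guest gives a linear (A_L-type) phase-solubility isotherm: total
dissolved guest S(C) = S0 + K·C, where S0 is the intrinsic guest
solubility, C the total host concentration, and the dimensionless slope
K = Ks·S0 / (1 + Ks·S0) < 1. Inverting gives the stability constant

    Ks = K / (S0 · (1 − K))   [M⁻¹].

**Fitting.** Both the Beer–Lambert calibration (absorbance vs
concentration) and the isotherm (solubility vs host concentration) are
unweighted ordinary least squares; there is no physical basis in this
context for weights, and the classic treatment uses plain OLS. The reported
r² is the squared Pearson correlation of each fit.

**Choices that affect the numbers.**

- *S0 from the fitted intercept*, not from the measured zero-host sample.
  The zero-host point stays in the fit; using the intercept makes Ks a pure
  function of the regression and is what reproduces the β-CD worked-example
  value of 275.5 M⁻¹ exactly. (Using the measured point instead shifts Ks
  by a few percent.)
- *Units*: concentrations are carried in mM everywhere and converted to M
  (×10⁻³) only inside `stability_constant`, so the slope is dimensionless by
  construction (both axes molar).
- *Dilution*: `dilution_factor` scales the inverted concentration,
  C = d·(A − b)/m, default 1.
- *A_L classification*: the isotherm is accepted as linear when the fit's
  r² ≥ 0.95 and 0 < K < 1. A slope outside (0, 1) is not an A_L isotherm
  and raises an error rather than returning a misleading Ks; r² below the
  threshold yields class "nonlinear" (higher-order complexation models such
  as A_P/A_N or Job plots are out of scope).
- *Negative computed solubilities* (absorbance below the calibration
  intercept) are retained with a warning: clipping would bias the OLS fit.

**Known data quirk.** The packaged 8-point rutin calibration reproduces the
published slope and intercept exactly, but its r² computed by any standard
OLS is 0.9857, not the 0.9833 printed alongside the curve in the original
report; the tests assert the recomputable value. Similarly, the Ks values
that follow from the packaged HP-β-CD and DM-β-CD rows (444.1 and
1085.7 M⁻¹) differ slightly from the originally reported 442.5 and
1012.4 M⁻¹ — consistent with intermediate rounding upstream — so only the
β-CD value and the stability *ordering* (DM > HP > β) are treated as exact.

## Trajectory data model

Structures and trajectories are orthorhombic-cell (or open-boundary)
collections of atoms with element, partial charge, molecule id/role and an
optional atom-class label. Coordinates are stored exactly as read —
possibly outside the box — and wrapping happens only inside distance
computations (minimum-image convention, per-component nearest image). This
matters because MSD must be computed from *unwrapped* coordinates; a
frame-to-frame jump exceeding half a cell edge triggers a wrapped-data
warning rather than silent corruption.

Formats: single/multi-frame XYZ whose comment line may carry
`time=<ps> cell=<a,b,c>`; minimal PDB (ATOM/HETATM + CRYST1, parsed with
gemmi, orthorhombic only); and a native CSV dialect (`frame, time_ps, atom,
element, x, y, z, charge, molecule_id, role[, class_label]`, optional
`# cell: a b c` header line) — the only dialect carrying charges, roles and
class labels. Atom indexing is 0-based internally; 1-based serials are
converted at the file boundary. Binary trajectory formats and triclinic
cells are out of scope.

## Mean square displacement

MSD(τ) = ⟨|rᵢ(t₀+τ) − rᵢ(t₀)|²⟩ averaged over selected particles. Two
origin schemes:

- `single`: t₀ = frame 0, the literal textbook definition.
- `multiple` (default): average over all valid time origins, computed with
  the standard FFT autocorrelation decomposition (O(T log T) per particle
  axis); statistically tighter, and tests assert its variance never exceeds
  the single-origin variance on Brownian replicas.

`estimate_diffusion` fits MSD(τ) by OLS inside a lag window and returns
D = slope/6 (3-D Einstein relation). The window is the caller's choice;
short lags are ballistic/noisy and long lags are origin-starved, so the
acceptance-scale Brownian check uses lags 10–100 ps of a 1000-frame run.

## Radial distribution function

g(r) = counts(r) / (n_frames · N_ref · ρ · 4πr²·dr) with minimum-image
distances, half-open uniform bins [r, r+dr) (bin centers reported, default
dr = 0.1 Å), self-pairs excluded when the two groups overlap, and
ρ = N_partner / V. The per-reference-atom normalization is included — the
plain dN/(4ρπr²dr) form sometimes quoted omits it — so the ideal-gas limit
is exactly 1, which is what interpretation of peak heights assumes. r_max
defaults to half the smallest cell edge and may not exceed it (the
minimum-image sphere). Frames are weighted equally; all generators here
produce constant-volume trajectories, so no NPT volume reweighting is
implemented. An independent cross-check against MDAnalysis' InterRDF on a
disjoint-group ideal gas agrees to ~1% (float32 coordinate storage in the
reference accounts for most of the residual).

Peak-position bands for interaction typing: hydrogen bond [2.5, 3.0) Å,
strong van der Waals [3.0, 5.0) Å, weak van der Waals ≥ 5.0 Å. Positions
below 2.5 Å are not covered by the published bands; they are reported as
hydrogen bonds with an "unusually short" warning rather than inventing a
fourth class.

## Hydrogen bonds

**Detection** is purely geometric: every hydrogen is covalently assigned to
its nearest donor-element atom within 1.2 Å (a standard O–H bond length
plus margin), and a D–H⋯A bond is recorded when the H⋯A minimum-image
distance is ≤ 3.0 Å and the D–H⋯A angle at the hydrogen is ≥ 120°. Defaults
restrict donors and acceptors to oxygen — the hydroxyl-rich chemistry of
cyclodextrins and flavonoids — and both the element sets and the two
thresholds are configurable. The 3.0 Å default is the upper edge of the RDF
hydrogen-bond band, keeping the two analyses consistent. Records are
flagged intra- vs intermolecular by molecule id. Detection is validated
against an exhaustive O(N²) plain-loop oracle on adversarial fixtures.

**Concentration**: C_HBs = N_HBs / (N_A·V), V converted from Å³ to cm³
(10⁻²⁴). For a trajectory, the per-frame count is reported as mean ± sd and
the mean is rounded to the nearest integer before the concentration is
formed. The published per-cell concentrations for the three cyclodextrin
cells are internally inconsistent with their own counts and volumes (143
bonds in a 19.2 Å cube is ≈ 3.4×10⁻² mol/cm³, an order of magnitude off the
tabulated value, and the prose ordering contradicts the table), so only the
arithmetic of the formula is asserted, never those tabulated numbers.

**Typing.** An atom-class table lists acceptor oxygen classes and
donor-hydroxyl hydrogen classes with partial charges (acceptors negative,
donor hydrogens positive — enforced). The catalogue of intermolecular bond
types is the cross-product guest-acceptors × host-donor-H followed by
host-acceptors × guest-donor-H, in table order, labelled A, B, C, …; this
ordering reproduces the conventional A–H labelling for the packaged
rutin/cyclodextrin table (six guest oxygens × one host hydroxyl class, plus
two host oxygens × one guest hydroxyl class = 8 types). Intramolecular
records and pairings absent from the catalogue are "untyped".
`rdf_per_type` computes one acceptor-class vs donor-H-class RDF per type,
which is how stable bond types are read off waterfall RDF plots.

## Energetics

**Binding energy** E_binding = −(E_total − E_guest − E_host), positive
favouring association. Component energies come either from a CSV table
(per-frame values averaged over a configurable trailing window, default 5
frames — the tail of an equilibrated run) or from the package's own
pairwise evaluator on synthetic systems.

**Pairwise nonbonded model** (for synthetic systems only): 12-6
Lennard-Jones with Lorentz–Berthelot mixing plus Coulomb
332.0637·qᵢqⱼ/r kcal/mol, unique pairs within a 12 Å default cutoff, no
tail corrections, minimum-image distances. This is a deliberately simple
toy force field — it exists so that binding-energy identities can be tested
exactly (under pairwise additivity, E_total − E_host − E_guest equals the
host–guest cross-pair sum to machine precision), not to approximate any
published force field; reproducing published binding-energy magnitudes for
the real complexes is explicitly not attempted (they depend on a commercial
force field and unshared trajectories).

**Solubility parameter** δ = √(ΔE/V), with the alternative vaporization
path ΔE = ΔH − R·T (R = 1.9872 cal/(mol·K)). Units are the field's
conventional cal-based ones: ΔE in cal/mol, V in cm³/mol, δ in (cal/cm³)^½.
Compatibility uses |δ_A − δ_B|: < 1.0 compatible, ≤ 3.4 may be compatible,
> 4.9 incompatible. The published rules are silent on (3.4, 4.9]; rather
than silently extending a neighbour, that gap is a fourth category,
"indeterminate". Boundary convention (the rules use strict inequalities):
1.0 and 3.4 fall into may_be_compatible, 4.9 into indeterminate. The rule
text is written with a signed difference but the worked examples tabulate
positive differences; the absolute value is used.

## Synthetic data: what it emulates and what it does not

All generators take explicit seeds and use one `numpy.random.Generator`
per call; reproducibility is bit-exact for a given library version.

- `simulate_isotherm`: the 1:1 A_L model with Beer–Lambert readout.
  Defaults mirror the worked example's design: host concentrations 0, 2, …,
  10 mM, a noiseless 8-point calibration over 0.02–0.09 mM, and 1%
  multiplicative absorbance noise (instrument-like; additive concentration
  noise would enter the fit differently). It does not emulate guest
  degradation, host self-association, or curved (A_P/A_N) isotherms.
- `brownian_trajectory`: free diffusion, i.i.d. Gaussian steps of variance
  2·D·dt per axis, unwrapped coordinates. No inertia, no interactions, no
  confinement — it validates the MSD/Einstein machinery, not cyclodextrin
  dynamics.
- `ideal_gas_frames`: uniform i.i.d. positions per frame; the exact g ≡ 1
  reference for RDF normalization.
- `hbond_fixture`: plants exactly k O–H⋯O geometries (H⋯A ∈ [1.8, 2.9] Å,
  angle ∈ [150°, 180°]) across host/guest molecules with class labels,
  plus decoys that narrowly fail the distance or angle test or lack a
  partner. Groups are confined to disjoint grid cells ≥ 11 Å apart, so no
  accidental cross-group bond can form and the ground-truth count is exact
  by construction; a too-small box raises rather than degrading.
- `two_cluster_system`: two random rigid clusters with the toy nonbonded
  model and exactly known component/cross energies by direct summation.

Consequently, passing tests demonstrate that the estimators and detectors
are correct *given their model assumptions* (linear isotherms, free
diffusion, geometric bonds, pairwise additivity); they say nothing about
force-field accuracy, sampling convergence, or real instrument error
structure.

## Problem sizes and numerical notes

The simulation-scale checks use 500 particles × 1000 steps (Brownian MSD,
slope recovered within 5%), 1000 atoms × 50 frames (ideal-gas RDF plateau
within ±5%), 100 seeded hydrogen-bond fixtures against the brute-force
oracle, and 200 noisy isotherm replicates (median Ks error ≤ 5% at 1%
noise) — sizes at which the statistical tolerances above are comfortably
stable across seeds while the whole suite runs in well under a minute.

Degenerate inputs fail loudly with typed exceptions: fewer than 2 calibration
points or zero concentration variance, isotherms without a zero-host point,
K outside (0, 1), non-positive S0 or molar volume, negative cohesive energy
(sign convention: ΔE = E_isolated − E_bulk > 0), r_max beyond half the cell
edge, open cells where a volume is required, and coincident atoms in the
pairwise evaluator. MSD at lag 0 is pinned to exactly 0 (clearing FFT
round-off); ties in Ks ranking preserve input order (stable sort).
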