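# hostguest

Analysis toolkit for cyclodextrin–flavonoid **host–guest inclusion
complexes**: phase-solubility analysis with stability-constant estimation,
molecular-trajectory descriptors (mean square displacement, radial
distribution functions, hydrogen-bond detection and typing), and energetics
(binding energy, Hildebrand solubility parameter, compatibility). A
synthetic-data module generates every input with known ground truth, so the
whole pipeline is testable without a wet lab or a commercial MD engine.

It is written for formulation and simulation scientists who study guest
solubilization by cyclodextrins (β-CD and its hydroxypropyl and dimethyl
derivatives) — the worked example throughout is the flavonoid **rutin** with
β-CD, HP-β-CD and DM-β-CD.

## The core quantities

**Stability constant.** A Beer–Lambert calibration `A = m·C + b` converts UV
absorbances of guest-saturated host solutions to guest solubilities. The
phase-solubility isotherm (guest solubility *S* vs host concentration *C*)
of a 1:1 complex is linear with slope *K* < 1 (Higuchi–Connors A_L type),
and the 1:1 stability constant is

```
Ks = K / (S0 · (1 − K))        [M⁻¹]
```

with *S0* the intrinsic guest solubility taken from the fitted intercept.

**Trajectory descriptors.** For particles in periodic orthorhombic boxes:
MSD(t) = ⟨|rᵢ(t) − rᵢ(0)|²⟩ (Einstein relation MSD = 6·D·t), the radial
distribution function g(r) = dN / (N_ref · ρ · 4πr²·dr) normalized so an
ideal gas gives g → 1, geometric hydrogen-bond detection (H⋯A ≤ 3.0 Å,
D–H⋯A ≥ 120° by default), and the molar hydrogen-bond concentration
C_HBs = N_HBs / (N_A·V). RDF peak positions classify interactions:
hydrogen bond (2.5–3.0 Å), strong van der Waals (3.0–5.0 Å), weak van der
Waals (≥ 5.0 Å).

**Energetics.** Binding energy E_binding = −(E_total − E_guest − E_host)
(positive favours association); Hildebrand solubility parameter
δ = √(ΔE/V) = √((ΔH − RT)/V) with the compatibility rule |δ_A − δ_B| < 1.0
(cal/cm³)^½ compatible, ≤ 3.4 may be compatible, > 4.9 incompatible.
Hydrogen-bond *types* are enumerated from partial-charge atom classes:
guest acceptor oxygens × host hydroxyl hydrogens, then host acceptors ×
guest hydroxyls, labelled A, B, C, …

## Worked example

```python
import hostguest as hg
from hostguest.datasets import load_calibration_series, load_isotherm_table

curve = hg.fit_calibration(load_calibration_series())
print(f"A = {curve.slope:.5f} C + {curve.intercept:.5f}  (r² = {curve.r_squared:.4f})")

table = load_isotherm_table()
named = []
for name, g in table.groupby("system", sort=False):
    iso = hg.build_isotherm(g["host_conc_mM"].to_numpy(),
                            g["absorbance"].to_numpy(), curve)
    named.append((name, iso))
    print(f"{name:12s} K = {iso.slope_K:.4e}  S0 = {iso.intercept_S0:.4e} mM "
          f"({iso.isotherm_class})  Ks = {iso.Ks:.1f} M⁻¹")
print("stability ranking:", " > ".join(hg.rank_by_ks(named)))
```

prints

```
A = 20.83333 C + 0.06792  (r² = 0.9857)
beta-CD      K = 1.3707e-03  S0 = 4.9823e-03 mM (AL)  Ks = 275.5 M⁻¹
HP-beta-CD   K = 2.4158e-03  S0 = 5.4531e-03 mM (AL)  Ks = 444.1 M⁻¹
DM-beta-CD   K = 3.3483e-03  S0 = 3.0943e-03 mM (AL)  Ks = 1085.7 M⁻¹
stability ranking: DM-beta-CD > HP-beta-CD > beta-CD
```

The calibration slope of 20.83 AU/mM means each mM of dissolved rutin adds
~20.8 absorbance units; the Ks values say a rutin molecule is bound roughly
275–1086 times more often than free at 1 M host, so DM-β-CD forms the most
stable inclusion complex and β-CD the least.

The same workflow is available from the shell:

```
hostguest calibrate --input cal.csv --out cal.json
hostguest phasesol --isotherm iso.csv --calibration cal.json
hostguest msd --traj traj.xyz --fit-window 10 100
hostguest rdf --traj traj.xyz --group-a class_label=O1 --group-b class_label=H2
hostguest hbonds --traj traj.csv --max-dist 3.0 --min-angle 120
hostguest compat --delta-a 12.650 --delta-b 12.422
hostguest run --config study.yaml --out results/
```

and `hostguest synth …` generates seeded synthetic inputs (isotherms,
Brownian/ideal-gas trajectories, hydrogen-bond fixtures, two-cluster energy
systems) in the same file dialects the readers consume.

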