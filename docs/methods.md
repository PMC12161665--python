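# Methods

## Scope and model

`aggpop` quantifies the speciation of a self-associating solute —
the reference system is phenol in carbon tetrachloride — as
populations of *interaction-pattern conformers*: equivalence classes
of aggregate geometries sharing the same functional-group contact
topology. Two functional groups per molecule are tracked, the
hydroxyl and the aromatic ring. Aggregates up to tetramers are
modelled; larger species are tallied (so the user can check they stay
rare) but excluded from classification and from the equilibrium
model, which assumes monomer ⇌ n-mer equilibria for n = 2–4 only.
That truncation is the model's main structural assumption: when
higher-order aggregates hold more than a few percent of the molecules
the derived constants absorb their mass into the n ≤ 4 species (the
CLI warns at 5%).

## Contact detection (C/d route)

Four contact classes are detected with geometric criteria, distances
strict ("<"), angle windows inclusive, all under the minimum-image
convention in an orthorhombic box:

| class | geometry | default |
|---|---|---|
| HB | O···H distance; O···H–O angle at H | < 2.6 Å; [135°, 180°] |
| π–π | ring-carbon centroid separation | < 4.0 Å |
| C–H···O | H···O distance; C–H···O angle at H | < 2.8 Å; [120°, 180°] |
| C–H···π | H···centroid; angle at H | < 3.0 Å; [120°, 180°] |
| O–H···π | H···centroid; angle at H | < 3.0 Å; [135°, 180°] |

All angle vertices sit at the hydrogen (the donor X–H bond versus the
H → acceptor direction); for O–H···π the vertex-at-H convention is a
package choice, as the alternative (vertex at O) is equally readable
from the phrase "O–H···π angle". Every threshold is a config value.

Group-level edges collapse to three classes: HB (hydroxyl–hydroxyl),
ππ (ring–ring: π-stacking and C–H···π) and OHπ (hydroxyl–ring:
O–H···π and aromatic C–H···O). Molecules joined by any contact form
the system adjacency matrix; connected components are the aggregates.

## Pattern classification

Aggregates containing at least one hydrogen bond are labelled by the
isomorphism class of their molecule-level H-bond graph — undirected
and simple, deliberately forgetting donor/acceptor identity. Canonical
forms are computed by exhaustive permutation (≤ 4! = 24), minimizing
the upper-triangle adjacency bit-string; identical codes iff
isomorphic, verified against a brute-force orbit enumeration in the
tests. H-bond-free aggregates fall back to "OHπ" when some molecule
touches its partners solely through hydroxyl–ring contacts, else
"ππ". The default catalog lists 3 dimer, 5 trimer and 10 tetramer
classes; the tetramer H-bond topologies are the eight graphs on four
vertices with 1–4 edges that a singly-donating hydroxyl can realize
(1-edge, two disjoint edges, 2-path, 3-path, star, triangle+isolate,
4-cycle, triangle+pendant). Topologies outside the catalog raise a
classification error naming the canonical code; the catalog is
user-extensible at runtime.

## Populations and equilibrium (C/d)

Per-frame counts N_nαj in volume V_j give
⟨C_nα⟩ = (1/N_steps) Σ_j N_nαj/(V_j N_A) and populations
P_nα = ⟨C_nα⟩/Σ_α⟨C_nα⟩ (a size with zero total is reported absent,
not zero). Self-association constants use the standard-concentration
convention K_n = ⟨C_n⟩(C°)^{n−1}/⟨C₁⟩ⁿ with C° = 1 mol L⁻¹, keeping
K_n a thermodynamic (loading-independent) quantity. Reported species
concentrations are then **re-solved** from mass conservation
Σ n K_n C₁ⁿ = C₀: f(C₁) is strictly increasing on [0, C₀], so Brent's
method on that bracket (plus a Newton polish) finds the unique root;
the tiny residual is absorbed into C₁ so Σ n·C_n = C₀ holds to
machine precision. Raw averages are emitted alongside for comparison.
Uncertainties come from block averaging over frames (10 blocks by
default) to respect trajectory autocorrelation.

## Free energies (Q/s route)

Each optimized isomer carries E_elec (counterpoise-corrected
upstream), ΔG_solv, harmonic frequencies and intensities, a PES
degeneracy m_i, symmetry number, mass and principal moments. Its
1 mol L⁻¹ solution free energy is

G* = E_elec + ΔG_solv + δG°_VRT + RT ln(RT/p°) + RT ln(M_solv C°/1000 ρ_solv).

δG°_VRT is ideal-gas rigid-rotor/harmonic-oscillator thermochemistry
referenced to the ground state (ZPE included), with the low-frequency
entropy replaced by Grimme's damped free-rotor interpolation
S = w·S_HO + (1−w)·S_FR, w(ν) = 1/(1+(ν₀/ν)⁴), ν₀ = 100 cm⁻¹ and
B_av = 10⁻⁴⁴ kg m² — the interpolation's originating defaults, both
exposed in config. Damping applies to entropy only; ZPE and thermal
energy stay harmonic. Frequencies are scaled by 0.96 before thermal
corrections (independently of the 0.96 spectral scale factor — the
two are separate config values that happen to share a default).

The standard pressure defaults to 1 atm, making the compression term
RT ln(RT/p°) the textbook 1.89 kcal mol⁻¹ at 298.15 K; with p° = 1 bar
it would read 1.90. The solvent density term defaults to CCl₄
(M = 153.82 g mol⁻¹, ρ = 1.5867 g cm⁻³), contributing −1.383 kcal/mol
at 298.15 K.

Isomers mapping to one pattern combine through the multi-well free
energy G({X}) = G(X_ref) − RT ln Σ_i m_i e^(−ΔG_i/RT), which is
provably independent of the reference member (tested to 1e-10) and
never above the best single well. m_i counts equivalent wells
including monomer-indistinguishability permutations; it is an input
field defaulting to 1 because no counting rule is imposed. Pattern
populations within a size are Boltzmann fractions of the G_nα,
computed shift-stably; K_n = e^(−(G_n − nG₁)/RT) uses the multi-well
G over *all* size-n isomers.

## Spectra

Harmonic sticks are scaled by 0.96 and broadened with unit-area
lineshapes: Gaussian (HWHM 60 cm⁻¹, σ = HWHM/√(2 ln 2)) for modes
whose *scaled* center falls in the O–H window [3200, 3650] cm⁻¹,
Lorentzian (HWHM 10 cm⁻¹, γ = HWHM) elsewhere. The lineshape is
chosen per mode, never per grid point, so bands keep one shape across
the window boundary. The window and widths are config values; the
wide Gaussian stands in for the inhomogeneous broadening of flexible
aggregates that a harmonic treatment cannot produce.

Intensities I (km mol⁻¹) convert to decadic molar absorptivity via
c = 10⁵/(ln 10·10³) ≈ 43.43 L mol⁻¹ cm⁻² — the convention that makes
Beer–Lambert dimensionally exact; integrated band areas conserve
c·ΣI to < 0.5% on an adequately wide grid (a warning flags grids that
truncate a band within 5 HWHM). Conformer bands are Boltzmann
averages of member-isomer curves; the total is
A(ω) = l Σ_n C_n Σ_α P_nα ε̄_nα(ω) with either route's populations,
and T = 10^(−A). The path length defaults to 0.05 cm and must be set
to the experimental cell for quantitative comparison.

## Synthetic data

The generators define the conditions under which the package is
validated:

* **Scenes** plant rigid, idealized aggregate templates — H-bond
  contacts at O···H ≈ 2.0 Å/180°, π stacks at 3.5 Å, O–H···π
  approaches at 2.8 Å/150° — with every non-planted contact clearing
  its cutoff by a safety margin, so the default 0.05 Å uniform jitter
  cannot flip a classification (templates are re-validated through
  the full pipeline at build time, and with zero jitter the
  pipeline-recovered composition equals the planted one exactly).
  Aggregates are packed by random insertion with ≥ 8 Å inter-aggregate
  atom separation (scene default; any value above the 4 Å maximum
  cutoff guarantees planted components stay separate). Solvent is an
  inert single-site placeholder, present only to exercise I/O.

* **Isomer tables** plant free-energy offsets through the electronic
  energy while holding all other terms identical within a size, so
  populations have closed-form Boltzmann ground truth.

* **Equilibrium trajectories** draw per-frame counts from independent
  Poisson distributions with means C_n·V·N_A (grand-canonical-like
  occupancy — the simplest model consistent with dilute equilibrium),
  using a 5.5 Å packing separation so molar loadings remain
  insertable. The bundled validation uses a 60 Å cubic box at
  C₀ = 0.45 mol L⁻¹ with 400–500 frames, sized so the rarest species
  (tetramers, ~0.14/frame) accumulates enough counts for a
  3-standard-error recovery test.

What the synthetic data does **not** emulate: physical force fields
and energetics, solvent structure, frame-to-frame correlation,
conformational flexibility within a pattern, and contact geometries
near the criteria boundaries. Passing tests therefore demonstrate the
correctness of the counting, classification, thermodynamic and
spectral machinery — not the adequacy of the geometric criteria or of
an MD ensemble for any real solution.

## Numerical choices

* Units: Å, amu, cm⁻¹, kcal mol⁻¹, mol L⁻¹, K internally; nm → Å and
  hartree → kcal mol⁻¹ conversion at the I/O boundary only.
* Minimum image: component-wise reduction to (−L/2, L/2], the exact
  half-box tie resolving to +L/2.
* Boltzmann sums subtract the minimum free energy before
  exponentiation (shift-stable); the multi-well log-sum is evaluated
  relative to the reference member.
* The equilibrium root uses Brent bracketing on [0, C₀] at 1e-15
  relative tolerance plus Newton polish; non-convergence is
  unreachable for the bracketed monotone polynomial.
* Degenerate inputs: empty frames, zero counts and all-zero K are
  valid (monomer-only); sizes with zero concentration are absent from
  population tables; imaginary frequencies, negative volumes and
  mismatched frequency/intensity lists are rejected at construction.
* Entropy comparisons in the stiff-mode limit are quoted in units of
  the gas constant: the harmonic entropy of a 3000 cm⁻¹ mode is
  ~10⁻⁵·R, so ratios against it are ill-conditioned while deviations
  in R-units track the damping weight (1 − w ≈ 1.2×10⁻⁶) directly.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* One hydroxyl and one ring per solute species; multi-group solutes
  would need a generalized group table.
* No anharmonicity beyond uniform frequency scaling; no hindered-rotor
  treatment; no electronic-structure or solvation computation — those
  quantities are inputs.
* Pattern classification forgets donor/acceptor direction by design;
  topologies distinguishable only by H-bond direction collapse.
* The equilibrium model ignores activity coefficients and n > 4
  species beyond tallying them.
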