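# aggpop

Populations of noncovalently bonded molecular aggregates — and the IR
bands they produce — for self-associating solutes such as phenol in
carbon tetrachloride.

Hydroxyl-bearing aromatic solutes self-associate through hydrogen
bonds, π–π stacking and O–H···π / C–H···O contacts, producing a
concentration-dependent mixture of monomers, dimers, trimers and
tetramers whose O–H stretching band broadens and red-shifts with
loading. `aggpop` quantifies that speciation by two independent
routes that share a single graph-based taxonomy of *interaction
patterns*:

* **C/d (classical/dynamic)** — count aggregates in trajectory
  snapshots. Contacts are detected with geometric criteria
  (O···H < 2.6 Å and 135–180° for hydrogen bonds, ring-centroid
  separation < 4.0 Å for π–π, H···O < 2.8 Å for C–H···O,
  H···centroid < 3.0 Å for X–H···π) under periodic boundaries; the
  molecule adjacency matrix is block-diagonalized into connected
  components; each aggregate of size n ≤ 4 is labelled by the
  isomorphism class of its hydrogen-bond graph (canonical form over
  ≤ 4! permutations), falling back to π–π / OH–π classes when no
  H-bond is present. Mean concentrations follow
  ⟨C_nα⟩ = (1/N_steps) Σ_j N_nαj / (V_j N_A), populations
  P_nα = ⟨C_nα⟩ / Σ_α ⟨C_nα⟩, and self-association constants
  K_n = ⟨C_n⟩(C°)^(n−1)/⟨C₁⟩ⁿ.

* **Q/s (quantum/static)** — Boltzmann-weight optimized isomers.
  Each isomer's standard-state solution free energy is
  G* = E_elec + ΔG_solv + δG*_VRT + RT ln(M_solv C°/1000 ρ_solv)
  with quasi-RRHO vibrational entropy (Grimme's damped free-rotor
  interpolation, ν₀ = 100 cm⁻¹) and the ideal-gas → 1 mol L⁻¹
  compression term RT ln(RT/p°) = 1.89 kcal mol⁻¹ at 298.15 K.
  Isomers sharing a pattern combine through the multi-well sum
  G({X}) = G(X_ref) − RT ln Σ_i m_i e^(−ΔG_i/RT), giving pattern
  populations P_nα ∝ e^(−G_nα/RT) and K_n = e^(−(G_n − nG₁)/RT).

Either K set closes the equilibrium model
C₁ + 2K₂C₁² + 3K₃C₁³ + 4K₄C₁⁴ = C₀ (unique positive root), and the
populations weight Boltzmann-averaged conformer spectra into the
Beer–Lambert total A(ω) = l Σ_n C_n Σ_α P_nα ε̄_nα(ω), reported as
transmittance T = 10^(−A). Harmonic sticks are scaled by 0.96 and
broadened with a 60 cm⁻¹-HWHM Gaussian inside the 3200–3650 cm⁻¹ O–H
window (inhomogeneous broadening of flexible aggregates) and a
10 cm⁻¹ Lorentzian elsewhere.

A synthetic-data module generates scenes with planted aggregates and
isomer tables with controlled free-energy gaps, so every stage is
testable with known ground truth and no external data.

## Worked example

Free-energy route on a synthetic isomer table in which the π–π dimer
lies RT·ln 9 above the OH-bonded one (`examples/03_qs_route.py`):

```
standard-state terms: gas->1M 1.89 kcal/mol, solvent density -1.383 kcal/mol

pattern free energies (multi-well, kcal/mol):
  n=2  OH-bonded  G =    -7.026  (2 isomer(s))
  n=2  ππ         G =    -5.308  (1 isomer(s))

populations (Q/s)   [analytic truth in brackets]:
  OH-bonded   94.78 %   [94.78 %]
  ππ           5.22 %   [5.22 %]

K2 = 0.998; at C0 = 0.115 mol/L the mixture is C1 = 0.0964, C2 = 0.0093 mol/L
```

The OH-bonded population exceeds the bare 90/10 Boltzmann split
because its second isomer (doubly degenerate, 0.4 kcal/mol up) deepens
the pattern's multi-well free energy. With K₂ ≈ 1, an 0.115 mol/L
solution keeps ~84% of molecules as monomers.

The other examples cover contact detection and classification
(`01_detect_and_classify.py`), equilibrium-constant recovery from a
synthetic trajectory (`02_cd_route.py`) and concentration-dependent
band synthesis (`04_spectra.py`). A thin CLI mirrors these workflows
(`aggpop synth | detect | classify | cd-populations | qs-populations |
equilibrium | spectrum | compare`).

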