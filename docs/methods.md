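# Methods

## Model and procedure

The package computes point-isotropic energy-absorption buildup factors
B(E, x) for multi-element materials by the geometric-progression (GP)
method. The chain is: (i) the material's Compton-to-total mass
attenuation ratio R(E) is formed by weight-fraction additivity from
elemental coefficients; (ii) R is matched against the pure-element
ratios for Z = 4–30 and the equivalent atomic number Zeq is obtained by
logarithmic interpolation between the two adjacent elements enclosing R;
(iii) each of the five elemental GP parameters a, b, c, d, Xk is
interpolated in log Z between ⌊Zeq⌋ and ⌈Zeq⌉; (iv) B follows from the
GP formula B = 1 + (b−1)(Kˣ−1)/(K−1) with
K = c·xᵃ + d·[tanh(x/Xk−2) − tanh(−2)]/[1 − tanh(−2)].

Assumptions inherited from the method: the medium is homogeneous and
effectively infinite, the source is point-isotropic, depth is measured
in mean free paths (so mass density never enters), and a mixture's
buildup behaviour is fully captured by the single energy-dependent
parameter Zeq — justified because buildup is dominated by multiple
Compton scattering, whose strength the ratio R tracks. The GP
representation is used strictly inside its stated domain x ≤ 40 mfp;
deeper depths are refused rather than extrapolated.

## Inputs and parameters

* **Compositions** — element → weight-fraction maps. Raw fractions must
  sum to 1 within ±2·10⁻³ (published tissue rows carry that much
  rounding); they are silently renormalized inside that band and
  rejected outside it. Element identity is the atomic number; symbols
  are resolved case-insensitively at parse time only. Water is carried
  as H 0.111898 / O 0.888102 (2:1 stoichiometry, standard atomic
  weights).
* **Elemental attenuation data** — CSV with per-(Z, energy) partial and
  total coefficients in cm²/g, covering at least Z = 4–30 and
  0.015–15 MeV. Totals must equal the sum of their declared partials to
  1·10⁻⁶ relative.
* **Elemental GP library** — CSV of (Z, energy, a, b, c, d, Xk) with a
  complete 25-energy grid per element (0.015–15 MeV, the grid of the
  elemental reference standard). GP parameters exist only on this grid;
  no energy interpolation of GP parameters is performed.
* **Coherent-scattering convention** — whether (μ/ρ)ₜ includes coherent
  (Rayleigh) scattering. Default: excluded, since coherent scattering
  does not remove photons and the mfp scale of buildup work is built on
  the removal cross section. The published Zeq values above ~1 MeV are
  sensitive to this choice and the original convention is not recorded,
  so both conventions are first-class
  (`AttenuationDataset(include_coherent=...)`, CLI `--include-coherent`)
  and the high-energy comparison is reported rather than asserted.

## Numerical choices

* **Energy interpolation** is linear in (ln E, ln μ) everywhere: exact
  at grid nodes and for power laws, monotone between nodes — the
  standard choice for photon cross sections. Non-positive bracketing
  values are an error, not a fallback.
* **Crossover energies** (Epe, Epp) are roots of ln μ_A − ln μ_B located
  by bisection in ln E to relative tolerance 10⁻⁶, after an audit that
  the difference changes sign exactly once across the tabulated nodes in
  the bracket; equality at a node returns that node. The search is
  symmetric in the two processes. "Pair production" means nuclear plus
  electron-field (triplet) contributions.
* **Zeq interpolation** uses natural logs (the base cancels). Ratios
  outside the elemental span are a hard error — the formula
  interpolates, never extrapolates. If the elemental ratio sequence is
  non-monotone (possible above ~1 MeV where R is nearly flat in Z) and
  several adjacent pairs enclose R, the pair with the smallest Z₁ is
  taken deterministically and the ambiguity is logged. Exact ratio
  matches short-circuit to the element (degenerate bracket), and R = R₁
  or R₂ returns Z₁/Z₂ exactly.
* **GP evaluation**: B(0) = 1 is taken as the algebraic limit without
  evaluating K (xᵃ diverges at 0 for a < 0); |K − 1| < 10⁻⁸ switches to
  the linear branch 1 + (b−1)x (removable singularity); K ≤ 0 is
  reported as an unphysical-parameter error. B(1) = b holds identically.
  Depths are arbitrary reals in (0, 40]; the packaged default depth set
  is {1–8, 10, 15, 20, 25, 30, 35, 40} mfp, matching the water
  reference tabulation.
* **Zeff** uses the direct cross-section-ratio method,
  Zeff = σₐ/σₑ with σₐ = (μ/ρ)ₘ / (N_A Σ wᵢ/Aᵢ) and
  σₑ = (1/N_A) Σ fᵢ (Aᵢ/Zᵢ)(μ/ρ)ᵢ over number fractions fᵢ; Avogadro's
  number cancels. Pure elements return Z exactly. Published Zeff curves
  for tissues were produced with a related interpolation-based variant
  whose exact form is not reproduced here; the divergence is documented,
  not resolved. Atomic masses are a built-in IUPAC table (Z = 1–40).
* **Tissue-equivalence bands** are maximal runs of consecutive grid
  energies with |ΔZeff|/Zeff(organ) ≤ tol (default 5%, configurable;
  the published screening is only qualitative). An absolute-difference
  mode makes the test symmetric under curve exchange. Evaluation is
  restricted to the supplied dataset's span — no extrapolation toward
  the keV/GeV extremes used in wide-range screening work.

## Synthetic data

Real XCOM-style attenuation tables and elemental GP libraries are
licensed tabulations that users supply; the test suite instead runs on
synthetic stand-ins (`gpbuildup.fixtures`) built so that every
interpolation stage has an exact oracle:

* `synthetic_attenuation`: photoelectric ∝ Z³·⁵ E⁻³, Compton
  ∝ (Z/A) E⁻⁰·²⁹ with A ≡ 2Z inside the model, coherent ∝ Z¹·⁵ E⁻²,
  pair ∝ (Z²/A) ln(E/1.022 MeV) above threshold. Defaults cover
  Z = 1–30 and 0.01–100 MeV and give a Compton-to-total ratio strictly
  decreasing in Z at every energy (so bracketing never fails) and a
  closed-form photoelectric/Compton crossover used to verify the
  bisection. Optional log-normal jitter requires an explicit seed;
  fixtures are deterministic by default.
* `synthetic_gp_library`: every parameter exactly linear in ln Z per
  energy, with b ≥ 1 and Xk > 0 by construction, so the log-Z
  interpolation recovers planted fractional-Z parameters to machine
  precision.

What passing on synthetic data does **not** show: agreement with real
cross sections (absorption edges, shell structure, the true energy
dependence of each process) or with the real elemental GP standard.
Those are covered separately: the published per-tissue GP parameter
tables, Zeq tables, crossover/peak energies and the water buildup
tabulation ship with the package at printed precision and are regressed
with last-digit tolerances, and the full element pipeline is validated
end-to-end when the user supplies real element tables (see README).

## Known limitations

* Energy-absorption buildup only; exposure (air-kerma) buildup, the
  Berger/Taylor/three-exponential forms and Monte Carlo transport are
  out of scope.
* With the printed, last-digit-rounded tissue parameters, the broad
  40-mfp buildup maximum can shift by one grid step where two grid
  energies are within a few percent (observed for one of the twelve
  tissues); the published peak energies are approximate.
* Recomputing percent differences from the printed water tabulation
  columns does not reproduce every printed percent value (those were
  evidently formed from unrounded factors); the stated maximum (4.29%)
  does reproduce and is the asserted bound.
* Zeq is only defined within Z = 4–30; materials whose ratio leaves
  that span (very low-Z media at high energy, high-Z media at low
  energy) are rejected rather than extrapolated.
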