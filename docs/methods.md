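# Methods

This note records the models implemented, the conventions and constants
chosen where the published analysis chain was ambiguous or internally
inconsistent, what the synthetic-data generators do and do not emulate, and
the known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mass budgets

Formula weights use IUPAC 2021 conventional (average) atomic weights to 3–4
decimals (`perichar.elements`); these reproduce every published formula
weight within 0.01 g/mol (ligands) to 0.05 g/mol (hydrated complexes).
Monoisotopic masses and isotopic fine structure are out of scope.

Parsing conventions: a count after `)` multiplies the group (`(SO4)2`); a
count after `]` begins a hydrate term (`…]3H2O` is three waters, never a
shell multiplier); a `·`/`.`/`*` separator before the hydrate is also
accepted. Element symbols resolve greedily against the active element table
with single-letter backtracking, so the TGA fragment shorthand `CON2` reads
as C+O+N₂; the default table deliberately omits cobalt and caesium to keep
that shorthand unambiguous. Supply a custom `ElementTable` to change this.

TGA stage containment is checked cumulatively against the running remainder
of the parent composition. Published decomposition schemes occasionally
over-assign a few atoms, so violations warn rather than fail by default
(`strict=True` restores hard errors); a negative total residue always
raises.

Labels: the analytical table's ligand mapping (L¹ = H, L² = 4-OMe,
L³ = 4-NO₂, L⁴ = 4-Cl, L⁵ = 3-Cl) is canonical throughout. The synthesis
section lists the chloro compound **3c** as L³ and the nitro compound **3d**
as L⁴ with swapped formula weights — an internal inconsistency of the
source; the analytical-table mapping is the one every downstream table
(TGA, ESR ordering, Hammett σ assignment) is consistent with.

## EPR bonding parameters

The analysis assumes an axially symmetric d¹ spin Hamiltonian with the
unpaired electron in d_xy (no nitrogen super-hyperfine), square-pyramidal
VO(II). Hyperfine magnitudes are stored positive in 10⁻⁴ cm⁻¹; the vanadyl
sign convention (A∥, A⊥ negative) is applied inside `fermi_contact_k` and
`beta_squared`, which is what makes their published values positive.

Two electron-g reference constants coexist in this analysis tradition and
are kept as separate named constants used exactly where the source uses
them: gₑ = 2.0023 (G, λ, k, β²) and 2.00277 (²K∥, ²K⊥ only).

**Spin-orbit constant.** The published text states g⊥ = gₑ − 2λ/E₂, which
gives λ ≈ 323 cm⁻¹ for the first complex — inconsistent with the λ = 138.18
cm⁻¹ the same analysis quotes and uses. The parallel-shift relation
g∥ = gₑ − 8λ/E₂ reproduces 138.18 to four significant figures from the
first complex's g∥ = 1.93 and E₂ = 15,290 cm⁻¹, and only a *single shared*
λ reproduces the p and ²K columns of all five complexes. `spin_orbit_lambda`
therefore implements the parallel-shift form, and the series analysis
(`pipeline.table4_derived`) derives λ once from the first complex.

**Known errata in the published parameter table.** Three cells are
internally inconsistent with the table's own formulas and inputs:

1. complex 3's A₀ prints 105.67 while (A∥+2A⊥)/3 = (168+138)/3 = 102.00
   (the printed value duplicates complex 4's cell);
2. complex 3's k (0.865) follows from that erroneous A₀
   (105.67/115.19 − 0.0523); the formula value is 0.830;
3. complex 4's p prints 114.00 while 7(171−73)/(6+1.5λ/12800) = 114.03.

The implementation computes from the formulas, so its golden-table test
reports exactly these three of 45 cells out of tolerance; they are left
failing deliberately rather than special-cased.

**α².** The printed expression α² = (2.0023 − Δg)/(8β²λ) with
Δg = (g⊥−g∥)·10⁻³ is dimensionally incoherent and does not reproduce the
tabulated α² column under any reading tried (the tabulated column tracks
−²K⊥ − 0.021, for which no printed formula exists). It is implemented
literally as `alpha_squared_literal`, flagged in its docstring, and
excluded from all golden comparisons.

## Conceptual-DFT descriptors

Closed-form arithmetic on (E_H, E_L); the module never converts units (the
source tabulates "eV" while the magnitudes resemble hartree — the indices
are reproduced on the tabulated scale either way). Softness: the tables
reproduce under S = η/2, not the common S = 1/2η; both conventions are
available (`softness_convention=`), the table convention is the default and
the golden tests pin it. Negative-gap inputs warn and propagate η < 0
rather than failing. The duplicated rows for the first and fourth complex
(identical frontier energies) are reproduced as published.

Hammett σ constants are not given in the source; a standard Hansch–Leo set
ships as editable config (H 0.00, 4-OMe −0.27, 4-NO₂ 0.78, 4-Cl 0.23,
3-Cl 0.37; σ_para for para substituents, σ_meta for 3-Cl). Because the σ
values are supplied rather than published, only the *sign* of the fitted
slope (positive: binding strengthens with electron withdrawal) is asserted
against the source.

## XRD crystallite metrics

The published size 6.003 (and δ = 0.0277 = 1/6.003²) is obtained only by
feeding the FWHM *degree number* into the Scherrer equation without
radian conversion. Both conventions are first-class (`mode="paper_degrees"`
reproduces the published numbers; `mode="radians"` is the default and gives
the physical ≈344 Å ≈ 34 nm, which is also the only reading consistent with
the source's own "nanometer range" remark). The two differ by exactly
180/π. The published strain 5.027 is not reproducible from the printed
single-peak rearrangement under any unit combination (the implementation
gives 0.0839 in raw-degree mode); strain output carries a docstring caveat
and is excluded from golden comparison. Scherrer constant K = 0.94,
λ(Cu Kα) = 1.5406 Å.

FWHM extraction (`peak_metrics`): baseline = minimum of the first/last 5 %
of samples; center = argmax with 3-point parabolic refinement; FWHM by
linear interpolation of the two half-maximum crossings. Single dominant
peaks only — no multi-peak or Rietveld analysis.

## DNA binding

The generator's binding model is the 1:1 isotherm f = K_b[DNA]/(1+K_b[DNA]),
ε_a = ε_f + (ε_b−ε_f)f — the unique model under which the Wolfe–Shimer
linearization is exact, making noiseless generator→fit round trips an exact
oracle (recovery ≤ 10⁻⁶ relative, tested across K_b ∈ [10³, 10⁷]). [DNA] is
in base pairs; the [DNA] = 0 point is excluded from fits by default; the
estimator is plain OLS (the slope/intercept recipe), not errors-in-variables.

Default generator conditions mirror the study design: ligand concentration
2×10⁻⁵ M, ε_f = 20,000 and ε_b = 12,000 M⁻¹cm⁻¹ (a 40 % hypochromic
contrast), ten [DNA] points on [10⁻⁵, 2.18×10⁻⁴] M. Under 1 % multiplicative
noise on ε_a the double-reciprocal transform amplifies noise roughly
four-fold (|ε_a−ε_f| is only 15–35 % of ε_a on this grid), so the median
relative K_b error over 500 replicates sits at 5–7 % — a property of the
published estimator under these conditions, reported as measured by the
test suite rather than smoothed over. What passing these tests shows is
that the *estimator chain* is correct; it does not validate the 1:1 model
against real titrations (none are available), nor address instrument
drift, dilution error, or wavelength-registration effects that real
spectra add.

## Synthetic data

All generators take an explicit seeded `GeneratorConfig`
(numpy `default_rng`; no global state); identical configs are bit-for-bit
reproducible. Peaks are Gaussian by default (no profile function is given
in the source), Lorentzian behind a flag; amplitude-0 and too-narrow-grid
degenerate paths raise. Compound sheets sample vanadyl-plausible tensor
ranges (g∥ < g⊥ < gₑ, A∥ > A⊥) and bound frontier pairs, for property-based
testing only — they do not emulate real correlation structure between
quantities.

## Numerical and testing choices

Rounding happens only at the reporting/comparison layer; all internal
computation is double precision. Golden comparisons use one unit in the
last printed decimal for the closed-form descriptor table (the source's own
rounding is inconsistent at the half-unit level in one cell) and ±0.01
(β² ±0.002) for the bonding-parameter table. Every closed-form operation is
cross-checked against an independent 50-digit mpmath re-evaluation on 1000
random valid inputs; regressions are cross-checked against the closed-form
normal equations. Problem sizes in the acceptance checks match the study:
10 compounds, 5 complexes, one diffraction peak, 10-point titrations with
500 noisy replicates per binding constant.
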