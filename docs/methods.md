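# Methods

## Electrostatic model

`tksa` scores surface charge–charge interactions with a
Tanford–Kirkwood-style sphere model attenuated by solvent accessibility
(TK-SA). The protein is a homogeneous sphere of dielectric ε_p centered at
the unweighted mean of all atom coordinates; its radius *b* is the maximal
atom-to-center distance plus a margin (default 2 Å), and mobile ions are
excluded from a concentric shell of radius *a* = *b* + 2 Å. Every ionizable
group is reduced to one point charge:

| group | placement | pKa |
|---|---|---|
| Asp | midpoint(OD1, OD2) | 4.0 |
| Glu | midpoint(OE1, OE2) | 4.4 |
| His | midpoint(ND1, NE2) | 6.3 |
| Lys | NZ | 10.4 |
| Arg | CZ | 12.0 |
| N-terminus | backbone N | 8.0 |
| C-terminus | midpoint(O, OXT), or O | 3.6 |

Cys/Tyr can be enabled but are off by default. Charges are either formal
(±1 for the predominant species) or Henderson–Hasselbalch fractions at the
working pH (default 7.0, titration mode on by default); both conventions
are exposed because published applications of this model family rarely
state which was used. Each charge's radial coordinate is capped at
*b* − 1 Å so it sits beneath the dielectric boundary, the classic TK-SA
parameterization.

The pairwise energy of sites *i*, *j* is

    W_ij = K q_i q_j (A − B − C)(1 − s_ij),   K = 1389.35 kJ·Å/mol

* `A = 1/(ε_p r_ij)` — direct Coulomb interaction inside the protein
  dielectric;
* `B = (1/b) Σ_{n=0}^{N} [(ε_p − ε_s)(n+1)] / [ε_p((n+1)ε_s + n ε_p)]
  ρⁿ P_n(cos θ_ij)` with ρ = r_i r_j / b² — the image-charge series for
  the dielectric boundary, evaluated with Legendre polynomials by upward
  recurrence; N = 30 by default, which agrees with N = 200 to better than
  10⁻⁶ kJ/mol on all tested geometries because ρ < 1 strictly;
* `C = (1/b) · x/(ε_s(1+x))`, x = κa, κ = 0.3287 √I Å⁻¹ — the
  leading-order Debye screening term. Higher ionic terms are omitted; they
  are small at the default I = 0.10 M and the ionic strength is
  configurable;
* `s_ij` — the arithmetic mean of the two residues' normalized
  accessibilities, clamped to [0, 1], so fully exposed pairs do not
  interact and buried pairs interact at full strength.

With ε_p < ε_s the bracket (A − B − C) is positive for all geometries we
generate, so the sign of W_ij is the sign of q_i q_j: like charges
destabilize. The per-residue score E_i = Σ_j W_ij satisfies
Σ_i E_i = 2 Σ_{i<j} W_ij.

Naming note: pairwise energies are called `W_ij` and per-residue aggregates
`E_i` throughout, to keep the two quantities (often conflated under a
single symbol in the applied literature) distinct.

## Solvent accessibility

Shrake–Rupley with a 1.4 Å probe and 960 test points per atom, using a
golden-spiral point set. The point set is deterministic and fixed in the
lab frame: results are bit-for-bit reproducible and exactly
translation-invariant, but rotating a structure changes individual atom
areas within the discretization error (a few percent at 960 points) — an
intrinsic property of any fixed finite point set, verified against the
isolated-sphere and two-sphere-cap closed forms. Hydrogens are ignored.
Per-residue areas are normalized by theoretical Gly-X-Gly maximal
accessibilities (Tien et al. 2013 values, in `tksa.constants`) and clamped
to [0, 1]. Exactly coincident duplicate atoms occlude each other completely
(area 0) rather than causing numerical trouble.

## Mutation design

Three filters, applied conjunctively (hence order-independent):

1. **Destabilization** — keep side-chain sites with E_i above a threshold
   (default 1.0 kJ/mol; "high positive" is inherently a tunable choice, so
   the threshold is exposed and logged rather than hard-coded).
2. **Catalytic safety** — drop sites whose charge point is closer than a
   cutoff (default 12 Å) to the nearest side-chain atom of any declared
   catalytic residue. The computed distance is reported per candidate so
   users can re-filter.
3. **Homolog support** — when an alignment is given, a proposed target
   residue is "supported" if observed at the aligned column in at least
   `min_count` homologs (default 1, the weakest defensible reading; the
   query row and gaps are excluded). Support is annotated, not enforced:
   the ranked report carries both the energy and the conservation evidence.

The substitution vocabulary is residue-class dependent: acidic sites →
{A, G (neutralize), K, R, H (reverse)}; basic sites → {A (neutralize),
D, E (reverse)}; His → {D (reverse), A (neutralize)}. After-mutation
energies keep the wild-type geometry and accessibility — no side-chain
rebuilding — which is consistent with a charge-model-level method and is
the main known limitation: predicted ΔE is an electrostatic score, not a
ΔΔG in physical units. Scoring recomputes only the mutated site's row of
the interaction matrix; a test verifies this equals a full matrix rebuild
to 10⁻⁹ kJ/mol. Ranking is ascending E_after, ties by descending E_before,
then residue number, so reports are deterministic.

Chain termini contribute charges to the field every site feels but are not
themselves mutable.

## Characterization fits

* **Inactivation half-life** — ordinary least squares of ln(activity) on
  time with free intercept (hence invariant to activity units); k = −slope,
  t½ = ln 2 / k. A non-negative slope is reported as "no measurable
  inactivation". Strictly first-order decay is assumed; partial
  renaturation after extreme heat challenge, which some β-sandwich
  glucanases show, is deliberately not modelled.
* **T50** — two-parameter descending logistic `a(T) = 1/(1+exp((T−t50)/s))`
  fit by Levenberg–Marquardt; with fewer than 4 points or on convergence
  failure it falls back to linear interpolation between the bracketing
  points, recording the method. Curves that never cross 0.5 are rejected.
* **DSC Tm** — a straight baseline fitted through the first and last 10%
  of the scan is subtracted; Tm is the grid maximum of the excess heat
  capacity refined by a parabola through the three surrounding points.
  A trace whose maximal excursion does not exceed 3× the baseline-window
  residual RMS is rejected as transition-free. Peak picking only — no
  two-state thermodynamic model.
* **Michaelis–Menten** — the double-reciprocal (Lineweaver–Burk) fit is
  the default, faithful to long-standing kinetics practice, and is exact on
  noiseless data. The `nonlinear` method fits v = Vmax·S/(Km+S) directly,
  seeded by the LB estimate and weighted relatively (σ ∝ v), the correct
  error model when assay noise is multiplicative; on noisy data it is
  substantially more accurate, especially when Km lies at or beyond the top
  of the substrate range, where the LB transform amplifies low-substrate
  noise. Both are reported by the CLI.
* **Catalytic efficiency** — kcat = Vmax × M/60 with Vmax in
  μmol/(min·mg) and M in kDa (= mg/μmol), giving kcat in s⁻¹ and
  kcat/Km in mL/(s·mg), the natural unit when polymeric substrates are
  dosed in mg/mL.
* **Comparison arithmetic** — `fold_change` supports both the plain ratio
  and the "increased N-fold" convention (ratio − 1) used in enzyme
  engineering reports; `percent_change` is 100 × (mut/wt − 1).

## Synthetic data

The generators emulate the statistical and geometric structure the
analysis assumes, with known ground truth:

* **Toy structures** — n charges rejection-sampled onto a shell at 0.9×
  the sphere radius with a minimum separation (default 5 Å), one residue
  per site (Lys/Asp/Gly for +1/−1/0) with a CA placed 2 Å inward and the
  charge atoms at the site position, emitted as a valid PDB. This gives the
  whole pipeline (read → extract → SASA → energies → scan) an end-to-end
  path with exactly known charges and positions. What it does not emulate:
  realistic packing, side-chain rotamers, buried charges, or correlated
  charge clusters of real proteins — so passing tests demonstrate
  correctness of the computation, not predictive accuracy on real
  structures.
* **Assay curves** — exponential decay, descending logistic,
  Michaelis–Menten, and Gaussian-peak-on-linear-baseline models on a
  declared grid, with seeded multiplicative Gaussian noise
  (y × (1 + ε), ε ~ N(0, σ)); σ = 0 gives exact curves. Default study
  designs: decay sampled 0–60 min every 5 min; tolerance curves 55–90 °C
  every 5 °C; substrate 0.25–5.0 mg/mL; thermograms 25–100 °C at 0.25 °C
  steps. Real assay noise is typically heteroscedastic in more complicated
  ways (pipetting, plate effects); 2% multiplicative noise is a clean
  idealization.
* **Toy alignments** — homologs copy the query except at declared columns,
  where residues are drawn from a declared set, so substitution support is
  known by construction.

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; repeated calls are byte-identical.

## Numerical choices and degenerate inputs

Coincident charges and empty structures raise immediately with the site
identities attached. Alternate locations resolve to the highest-occupancy
conformer; insertion codes are rejected (the intended inputs are
single-model monomeric structures). The Legendre series uses upward
recurrence (stable for |cos θ| ≤ 1). Interaction matrices are evaluated
pair-by-pair; at the intended scale (hundreds of ionizable sites) this is
far from any performance limit. All coordinates are in Å and all energies
in kJ/mol. Floating-point output in reports is printed to 6 significant
digits to keep diffs stable.

## Problem sizes used in the test and acceptance runs

Toy structures of 2–20 sites; SASA convergence checks on 20-atom clusters;
noisy-recovery statistics over 200 replicates per fit at 2% noise. These
sizes fully exercise every code path while keeping the whole suite under a
minute on one CPU.
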