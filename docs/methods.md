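# Methods

## The model

`concordant` computes harmonic vibrational frequencies with the Concordant
Mode Approach (CMA). The setting: one wants the harmonic spectrum of an
expensive electronic-structure level (Level A), but full Level-A Hessians
scale poorly. A cheaper Level B supplies a normal-mode basis **Q**_B via
the Wilson GF method in a complete, nonredundant set of natural internal
coordinates (NICs) **S**:

- **B** = ∂S/∂x (Wilson B matrix), **G** = **B u B**ᵀ with **u** the
  reciprocal-mass diagonal;
- the GF eigenproblem **GF**_B **L**_B = **L**_B Λ_B defines the Level-B
  modes through **S** = **L**_B **Q**_B.

The CMA ansatz writes the Level-A field in that basis,
**F**_A = (**L**_B⁻¹)ᵀ **F**_CMA(A) **L**_B⁻¹. Because normal modes
diagonalize the Level-B problem, **F**_CMA(A) is strongly diagonally
dominant, and truncations of it define the protocol hierarchy:

- **CMA-0**: diagonal elements only;
- **CMA-1(n)**: diagonal plus n hand-picked couplings;
- **CMA-2**: diagonal plus couplings selected automatically by the ξ
  diagnostic computed from a third, still cheaper Level C.

The premise behind CMA-2 is that the couplings that move when the theory
level steps C → B are the ones expected to move again stepping B → A, so
the off-diagonal structure of **F**_CMA(C) acts as a "photographic
negative" of **F**_CMA(A). Elements with ξ strictly greater than a user
cutoff are included; the transformation becomes exact when all elements
are included, and selections are nested in the cutoff, so the method
converges monotonically in cost.

### The ξ normalization is an interpretive choice

The package defines, by default,

ξ_ij = |F^C_ij| / √(|F^C_ii| · |F^C_jj|)  (i ≠ j, ξ_ii = 0),

i.e. each Level-C coupling measured against the geometric mean of its
diagonal partners, with absolute values guarding sign anomalies. This
satisfies the defining constraints (dimensionless, scale-invariant,
relative to the associated diagonal force constants) but is one of several
formulas that do; an alternative normalizing by the Level-B eigenvalues
(`lambda_b`) is selectable, and the strategy used is always recorded in
the `XiMatrix` provenance. Results quoted by this package always state the
normalization.

## Coordinates and transformations

Primitives: bonds (Å), angles, torsions (IUPAC sign, range (−π, π], values
at the branch cut reported as +π), signed out-of-plane wags
γ(i,j,k,l) ∈ [−π/2, π/2] (positive on the (j→k)×(j→l) side of the plane),
and linear bends for quasilinear fragments. A linear bend measures
deviation from linearity against a reference perpendicular ŵ frozen at the
reference geometry; degenerate pairs get two perpendicular ŵ. All B-matrix
rows are analytic gradients, validated against five-point numerical
differentiation.

NIC rows are normalized to unit Euclidean norm on load (raw coefficients
retained for provenance) so that "a displacement of 0.01 in NIC units" is
well defined; published coordinate tables list unnormalized combinations
and do not fix a normalization, so unit norm is this package's choice.

The GF solution uses the symmetric square root **W** of **G**
(**L** = **W C** with **C** the orthonormal eigenvectors of **W F W**),
giving **L**ᵀ**F L** = Λ and **L**ᵀ**G**⁻¹**L** = **I** simultaneously.
Any convention consistent with **S** = **L Q** yields identical
frequencies (asserted by test). Eigenvalues convert to wavenumbers through
a CODATA-assembled constant (≈ 1302.79 cm⁻¹ per √(aJ Å⁻² amu⁻¹));
imaginary modes are encoded as negative cm⁻¹.

Cartesian Hessians enter the internal basis via F_S = A F_x Aᵀ,
A = **G**⁻¹**B u**. The gradient-dependent term is omitted — the transform
is intended for optimized reference geometries — and a warning fires if a
supplied gradient norm exceeds 1e−6 aJ/Å.

The back-transformation maps δ**Q** (or δ**S**) to Cartesians by iterating
δx = **u B**ᵀ**G**⁻¹ ΔS with **B**, **G** refreshed each step (max 50
iterations, residual tolerance 1e−12 in NIC units); torsions are unwrapped
toward their reference branch so displacements across ±π stay continuous.

## Finite differences

Force constants are taken from energies on displaced geometries generated
through the curvilinear back-transformation. Default step 0.01 NIC units
(0.005 also customary), default accuracy order 4:

- diagonal: 5-point stencil (−1, 16, −30, 16, −1)/12h²;
- off-diagonal: tensor product of the 4-point first-derivative stencil
  (1, −8, 8, −1)/12h over offsets (±1, ±2) in each coordinate (16
  energies). The literature fixes only the order of accuracy, not the
  cross stencil; this product form is exact for polynomials through
  degree 5 and is validated by the polynomial and Richardson tests
  (error ratio 16 on a sextic when h is halved).

Plans are deterministic (stable job ordering, deduplicated labels, the
reference geometry exactly once) and serialize to JSON so energies can be
computed out-of-band by any engine; the package itself never invokes an
electronic-structure code — adapters satisfy a plain label→energy map
contract. Engine convergence settings are adapter configuration, not
package logic. Assembled fields mark unrequested elements *absent*, not
zero.

Symmetry enforcement zeroes every element coupling coordinates or modes
of different irreducible representations; modes that are sole inhabitants
of an irrep are then exact under any CMA mask, and whole irrep blocks
decouple (the pyridine a₂ block is the packaged demonstration).

## Mode matching and reporting

Per-mode residuals ϵ_k = ω_CMA,k − ω_ref,k require pairing the two mode
sets. Columns of **L** are orthonormal under the **G**⁻¹ metric, so
**O** = **L**_refᵀ**G**⁻¹**L**_CMA is a near-orthogonal overlap matrix;
matching is greedy on |O| restricted to equal-irrep pairs, with a
frequency-order fallback when two candidates overlap within 1e−6.
The cost metric η = 100·|selected couplings| / (vibrational DOF), full
precision internally, nearest integer in reports. Outliers are residuals
above 1.5 cm⁻¹ in magnitude. ZPVE = ½Σω; its residual equals ½Σϵ by
linearity. Summary statistics: MAE, mean, sample (n−1) standard deviation,
ϵ_max (mean per-molecule max |ϵ|) and ϵ_MAX (global max |ϵ|).

Total energy distributions use the standard eigenvector-weighted
decomposition TED_ki = 100·L_ik(F_S L)_ik/λ_k (the percentage of mode k's
energy on coordinate i, signs recording eigenvector phases; rows sum to
100). Reports filter entries below 5 % by default. The originating
literature cites a formula not reproduced in accessible text; this
standard decomposition is adopted and labeled as such.

## Synthetic study systems

The generator produces what the tests and the acceptance script measure
on: bent/linear triatomics, six-rings and carbon chains with complete
NIC sets and positive-definite quadratic NIC-space potentials (stretch
diagonals 4–8 aJ Å⁻², bends 0.3–1.2 aJ rad⁻², torsions 0.05–0.35,
couplings up to 8 % of the geometric-mean diagonal — ordinary magnitudes
for covalent molecules). Level triples are derived as

F_B = F_A + α·Δ,  F_C = F_B + β·(ρ·(−Δ) + (1−ρ)·noise),

with Δ a sparse symmetric perturbation scaled by √(F_ii F_jj), defaults
α = β = 0.03, sparsity 0.5 and ρ = 0.9. These place the ξ diagnostics in
the 0.005–0.2 operating range typical of real multi-level force fields and
give the C field a strong but imperfect correlation with the A−B coupling
difference — the regime CMA-2 is designed for. α is halved automatically
(and logged) if F_B would lose positive definiteness. All generators draw
from one named `numpy` generator per call; output is bit-reproducible
from (parameters, seed).

What the generator does *not* emulate: basis-set or correlation physics,
anharmonicity, Fermi resonances, or the systematic (rather than random)
structure of real level-to-level differences. Passing tests therefore
demonstrate the correctness and convergence of the machinery and the
statistical advantage of ξ-guided selection under the stated correlation
model — not the quantitative error statistics any particular pair of
electronic-structure levels would give.

The packaged pyridine and 1-(1H-pyrrol-3-yl)ethanol fixtures carry the
standard chemically intuitive NIC sets for those molecules (27 and 45
coordinates; both verified complete and nonredundant at the shipped
geometries). The geometries are clearly-labeled idealized placeholders
(planar hexagon; an MMFF94-relaxed conformer) — sufficient for exercising
coordinates, symmetry blocks and transformations, not reference
structures. The five-ring combination coefficients use the ideal pentagon
values cos/sin of 2π/5 and 4π/5. Full G2-style benchmarking against real
electronic-structure data is supported through the Hessian-file and
plan/assemble interfaces but sits outside the test suite by design.

## Numerical choices

- Rank/zero tolerance: singular values below 1e−8 × (largest) count as
  zero in redundancy checks.
- Force-constant symmetry is required to 1e−12 (relative) on input;
  matrices are then symmetrized exactly.
- Non-positive-definite **G** is an error (redundant/incomplete set);
  **L** condition numbers above 1e10 warn.
- Degenerate eigenvalues: stable descending-frequency sort plus a sign
  convention (first significant eigenvector component positive).
- Strict ">" comparison at the ξ cutoff; cutoff = ∞ reproduces CMA-0
  exactly.
- Problem sizes: the acceptance script uses 50 ensemble systems of
  dimension 3–12 with two random-selection draws per system, enough to
  separate ξ-guided from random selection cleanly while keeping the run
  in seconds.

## Known limitations

- Automatic NIC generation from connectivity is out of scope; coordinate
  files are authored by the user (or shipped fixtures).
- Redundant-coordinate machinery, anharmonic (VPT2) corrections and
  rotational analysis are not implemented.
- Linear-bend reference axes are space-fixed at the reference geometry;
  rigid-rotation invariance of those rows holds only at linear reference
  configurations, the single geometry class that needs them.
- Mode irrep labels are inherited from the dominant symmetry-adapted
  coordinate component — a heuristic that is exact once cross-irrep blocks
  are enforced to zero, and indicative otherwise.
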