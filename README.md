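# concordant

Harmonic vibrational frequencies by the **Concordant Mode Approach
(CMA)**: compute an expensive (Level A) force field in the normal-mode
basis of a cheap Level B theory, where it is nearly diagonal, and evaluate
only the couplings that matter.

The package is aimed at computational spectroscopists who want
coupled-cluster-quality harmonic frequencies for molecules where full
high-level Hessians are out of reach. It implements:

- **Wilson GF machinery** in natural internal coordinates (NICs): analytic
  B matrices for bonds, angles, torsions, out-of-plane wags and linear
  bends; G = B u Bᵀ; the GF eigenproblem with S = L_B Q_B; iterative
  curvilinear back-transformation of normal-mode displacements to
  Cartesians.
- **The CMA hierarchy.** With F_CMA(A) = L_Bᵀ F_A L_B, the protocols keep
  the diagonal only (CMA-0), the diagonal plus hand-picked couplings
  (CMA-1), or the diagonal plus couplings selected automatically (CMA-2)
  by the dimensionless diagnostic

      ξ_ij = |F^C_ij| / sqrt(|F^C_ii| |F^C_jj|),   i ≠ j,

  computed from a still cheaper Level C field in the Q_B basis. Elements
  with ξ above a user cutoff are evaluated explicitly; the method is
  exact when all couplings are included and converges monotonically as
  the cutoff tightens.
- **Finite differences** of energies in the NIC (or Q_B) basis with
  fourth-order stencils, displacement plans that serialize to JSON for
  out-of-band energy evaluation by any electronic-structure engine, and
  strict symmetry enforcement by irrep labels.
- **Analysis**: per-mode residuals ϵ = ω_CMA − ω_ref via overlap-based
  mode matching, the cost metric η (couplings as % of vibrational DOF),
  ZPVE residuals, total energy distributions (TEDs), benchmark summary
  statistics and cutoff-convergence curves.
- **Synthetic study systems**: seeded generators for molecules, complete
  NIC sets, quadratic potentials and correlated Level A/B/C force-field
  triples, so the entire pipeline is testable without any quantum
  chemistry engine.

## Worked example

Generate a synthetic study system (a 5-atom chain with correlated Level
A/B/C fields) and run CMA-2 with a ξ cutoff of 0.02:

```sh
concordant synth --kind chain --n 5 --seed 3 --out demo
concordant cma2 --xyz demo/geometry.xyz --nic demo/coords.nic \
    --fa demo/hessian_A.dat --fb demo/hessian_B.dat \
    --fc demo/hessian_C.dat --cutoff 0.02 --no-symmetry --out demo_run
```

which prints

```
cma2: eta = 133%, MAE = 0.0653 cm-1, max|eps| = 0.2578 cm-1 -> demo_run
```

Read: 12 off-diagonal couplings were selected (133 % of the 9 vibrational
degrees of freedom — this system's couplings are comparatively dense), and
with only those couplings the Level-A spectrum is reproduced to a mean
absolute error of 0.07 cm⁻¹ (worst mode 0.26 cm⁻¹). `demo_run/report.json`
holds the reference and CMA frequencies, residuals, selected pairs and the
ξ matrix; `demo_run/frequencies.csv` is the human-readable table. Running
`cma0` instead gives the diagonal-only baseline, and `--fb demo/hessian_A.dat`
(Level B = Level A) gives identically zero residuals — the built-in sanity
check of the ansatz.

The same protocols are available as library calls (`concordant.run_cma`),
and `concordant plan` / `concordant assemble` handle finite-difference
force constants from energies computed elsewhere. Packaged pyridine and
1-(1H-pyrrol-3-yl)ethanol coordinate sets (27 and 45 NICs, with irrep
labels) ship as fixtures: `concordant.load_fixture("pyridine")`.

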