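# genarith

Kinetic-order inference for power-law (S-system) models of
end-product-inhibition cascades, using lattice cones and Hilbert bases of
affine monoids.

A length-`n` cascade is a chain `X1 -> X2 -> ... -> Xn` whose end product
inhibits the first (allosteric) step. In the power-law formalism the feedback
strength is a kinetic order `g`, interpreted as a number of binding sites.
Classic power-law analysis cannot infer `g`; this package implements a
geometric route:

1. **powerlaw_cascade** — build/solve/simulate the S-system (exact log-linear
   steady states, stiff log-space ODE integration, Jacobian eigenvalue
   stability classification).
2. **exponent_lattice** — rewrite each equation as homogenized exponent-space
   lattice vectors, assemble per-species lattice-cone matrices
   (lexicographically ordered originals with adjacent-pair difference rows),
   and sample square integer dual matrices (deterministic shortest-vector mode
   by default; seeded Boltzmann `exp(-|v|^2/T)` sampling optional).
3. **hilbert_monoid** — compute the Hilbert basis of the dual monoid
   `{v : <v, row> >= 0} ∩ Z^d` natively (equality-pair reduction, simplicial
   start via Smith-normal-form parallelepiped enumeration, Pottier halfspace
   completion, degree-graded irreducibility reduction), plus Normaliz
   plain-text `.in`/`.out` interchange and an optional external-binary
   cross-check backend.
4. **genotype_arithmetic** — pair the symbolic feedback lattice vector
   `b(g) = (1, 0, ..., 0, g, 1)` with the basis vectors; finiteness of the
   monomial limits at the torus boundary gives affine inequalities in `g`
   whose solution is the admissible range. The per-cone bases are completed to
   permuted identity matrices and aggregated into an exactly bistochastic
   matrix (divisor = species cones + constraint cones, e.g. `7 + 1 = 8` for
   `n = 7`), whose entries are genotype/phenotype occupancy ratios.
5. **cli / reporting / fixtures** — command line, report writers (JSON, CSV,
   text), comparison table, deterministic fixture generation.

The geometric constraint system bounds `g` from below; the upper bound in
practice comes from dynamics, so every report carries the eigenvalue-based
stability classification per integer candidate and the comparison table can
include the numerically bisected stability boundary (which reproduces the
classic `sec(pi/n)^n` law for symmetric rates).

Note: two divisor conventions appear in the source analysis's prose; this
package always uses the arithmetically consistent rule
`divisor = #species cones + #constraint cones`.

## CLI

```sh
# full prediction pipeline for n = 7 (writes report.json / .csv / .txt)
genarith predict --length 7 --seed 42 --outdir report_n7

# time course (t, X1..Xn CSV; optional PNG)
genarith simulate -n 7 --g 1 --t-end 120 --out traj.csv

# Hilbert basis of a cone file (rows = inequality generators)
genarith hilbert cone.in --json-out basis.json

# deterministic fixtures; comparison table for n = 3..9
genarith fixtures --seed 0 --outdir fixtures
genarith compare --lengths 3-9 --out comparison.csv
```

Cone files use the classic plain Normaliz dialect (row count, column count,
integer rows, trailing input-type keyword). The native `hilbert` semantics
treat the rows as inequalities (Normaliz input type `inequalities`).

## Layout

```
src/genarith/
  powerlaw_cascade.py    S-system models, steady states, simulation, stability
  exponent_lattice.py    lattice vectors, cone matrices, dual-matrix sampling
  hilbert_monoid.py      cones, dual cones, Hilbert bases, Normaliz IO
  genotype_arithmetic.py constraints, g-range, bistochastic aggregation, pipeline
  config.py / reporting.py / fixtures.py / cli.py
tests/                   unit, property (hypothesis) and acceptance suites
scripts/acceptance.py    acceptance target recomputation
```
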