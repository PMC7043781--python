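# critnet

Criticality analysis of protein residue contact networks: elastic-network
normal modes, long-range correlation statistics, graph-topology descriptors,
and the finite-size scaling fits that place native proteins between ordered
lattices and disordered polymers.

## The scientific problem

Native globular proteins fluctuate around their folded state with
correlations that reach across the whole molecule — the structural basis of
allostery and long-range signalling. A minimal structure-based account of
these fluctuations is the Gaussian network model (GNM): one node per residue
(its Cα atom), a unit spring between every residue pair closer than a cutoff
r_C, and Gaussian fluctuations governed by the Kirchhoff matrix Γ (the graph
Laplacian of the contact network),

    Γ_ij = −1 if r_ij ≤ r_C (i ≠ j),    Γ_ii = degree of i.

From Γ the package computes:

- **Normal modes.** Eigenvalues of Γ (λ ∼ ω²) and of the symmetric
  normalized Laplacian L = D^{−1/2} Γ D^{−1/2}, whose spectrum is comparable
  across system sizes; the slowest nonzero mode λ₁ and the mode density g(λ).
- **Correlations.** Covariance C = Γ⁺ (pseudoinverse; prefactor 3k_BT/κ set
  to 1), cross-correlations φ_ij = C_ij/√(C_ii C_jj), the distance-dependent
  correlation function φ(r), the correlation length ξ (first zero crossing
  of φ), and the finite-size susceptibility
  χ = (s/N) Σ_{i<j} φ_ij θ(ξ − r_ij).
- **Topology.** Average shortest-path length ⟨l⟩ and Louvain-maximized
  Newman modularity Q of the binary contact graph.
- **Geometry.** Radius of gyration R_g and the shape factor
  s = N a³/(L₁L₂L₃) (a = 3.8 Å; L_i the principal semi-axes of the inertia
  ellipsoid).
- **Scaling.** Log-log power-law fits across size ladders: λ₁ ∼ N^{−ζ},
  ⟨l⟩ ∼ N^α, Q = 1 − K·N^{−η}, ξ vs R_g, χ ∼ N^{αγ/ν}; and the effective
  dimension d_eff = 1/η − 1 implied by the modularity law η = 1/(d+1).

Protein behaviour is benchmarked against two generated reference systems:
near-spherical fcc lattice clusters with springs to the first and second
neighbour shells (the ordered limit) and ideal freely-jointed polymer chains
with a 3.8 Å bond (the disordered limit). Lattices scale with ζ close to the
elastic-theory value 2/3 and η below 1/4; polymers show much steeper mode
softening (ζ ≈ 1.7) and a strongly fractal modularity scaling (η ≈ 0.46,
d_eff ≈ 1.15). Proteins fall between the two — the "critical point" reading
of native-state dynamics.

## Worked example

Analyze one generated fcc cluster of 500 sites end to end:

```python
from critnet import GeneratorSpec, run_structure

rec = run_structure(GeneratorSpec("fcc", 500))
print(rec.n, rec.rg, rec.lambda1, rec.mean_path, rec.q, rec.xi, rec.chi)
```

prints (rounded)

```
n          = 500
rg         = 12.9237    # radius of gyration, A
s          = 5.9082     # shape factor: lattice packing is far denser than proteins
lambda1    = 0.1507     # slowest nonzero mode, normalized Laplacian (r_C = 9 A)
lambda1_raw= 7.4453     # same mode on the raw Kirchhoff spectrum
mean_path  = 3.0019     # average shortest-path length (r_C = 8 A)
q          = 0.4920     # Louvain-maximized modularity, 7 communities
xi         = 13.9609    # correlation length, A — comparable to the cluster size
chi        = 10.0392    # susceptibility
```

Note ξ ≈ R_g: even in this minimal model the correlation length extends to
the size of the whole system. Fitting the slow-mode scaling over a cluster
ladder:

```python
from critnet import fcc_mode_scaling
fit = fcc_mode_scaling(sizes=(128, 256, 512, 1024))
print(fit.exponent, fit.stderr_exponent, fit.r_squared)
# 0.688  0.009  0.9996     -> lambda_1 ~ N^-0.69, near the elastic value 2/3
```

The same operations are exposed on the command line:

```
critnet generate --kind chain --n 500 --seed 1 --out chain.xyz
critnet analyze chain.xyz --rc 9 --out row.tsv
critnet scaling --table records.tsv --y lambda1 --negate
critnet reproduce --suite lattice
```

For PDB input, `critnet analyze structure.pdb --chain A` runs the identical
pipeline on the Cα trace of one chain (fixed-column PDB, first model,
chain-length window 30–1200 applied in dataset runs). Single-file protein
checks that require downloading coordinates — e.g. the shape factors of the
PDB entries 1OCY (s ≈ 0.84) and 5CWG (s ≈ 2.37), or the protein exponents
⟨l⟩ ∼ N^0.338 and λ₁ ∼ N^{−1.074} over a large X-ray dataset — run through
this same entry point but are not part of the offline test suite.

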