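"""Generators for the ordered and disordered reference systems.

Protein scaling behaviour is benchmarked against two limiting cases:
near-spherical fcc lattice clusters (the ordered, densely packed limit) and
ideal freely-jointed polymer chains (the disordered, expanded limit), plus
full cubic lattices for the theoretical modularity benchmark.  All
generators default to a 3.8 A nearest-neighbour/bond spacing so the same
contact cutoffs used for C-alpha traces transfer directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures_io import CoordinateChain, RESIDUE_SIZE


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one reference structure."""

    kind: str  # 'fcc' | 'cubic' | 'ideal_chain'
    n_target: int
    spacing: float = RESIDUE_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fcc", "cubic", "ideal_chain"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n_target < 8:
            raise ValueError("n_target must be >= 8")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def build(self) -> CoordinateChain:
        if self.kind == "fcc":
            return generate_fcc_cluster(self.n_target, spacing=self.spacing)
        if self.kind == "cubic":
            d = max(2, round(self.n_target ** (1 / 3)))
            return generate_cubic_lattice((d, d, d), spacing=self.spacing)
        return generate_ideal_chain(self.n_target, bond_length=self.spacing, seed=self.seed)


def generate_fcc_cluster(n_target: int, spacing: float = RESIDUE_SIZE) -> CoordinateChain:
    """The ``n_target`` fcc sites nearest the origin (a near-spherical cluster).

    fcc sites are the integer triples with even coordinate sum, scaled by
    spacing/sqrt(2) so the nearest-neighbour distance equals ``spacing``.
    Sites are ranked by distance from the central site with a lexicographic
    tie-break, which makes the carving deterministic.
    """
    # Candidate box comfortably larger than the target sphere.
    m = int(np.ceil((3.0 * n_target) ** (1 / 3))) + 3
    r = np.arange(-m, m + 1)
    i, j, k = np.meshgrid(r, r, r, indexing="ij")
    sites = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1)
    sites = sites[(sites.sum(axis=1) % 2) == 0]
    d2 = (sites**2).sum(axis=1)
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0], d2))
    chosen = sites[order[:n_target]] * (spacing / np.sqrt(2.0))
    return CoordinateChain(
        points=chosen,
        source_id=f"fcc:n={n_target}:a={spacing:g}",
        is_chain=False,
    )


def generate_cubic_lattice(dims, spacing: float = RESIDUE_SIZE) -> CoordinateChain:
    """Full rectangular grid with N = dims[0] * dims[1] * dims[2] sites."""
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 2 for d in dims):
        raise ValueError("dims must be three integers >= 2")
    ax = [np.arange(d) * spacing for d in dims]
    i, j, k = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1)
    return CoordinateChain(
        points=pts,
        source_id=f"cubic:{dims[0]}x{dims[1]}x{dims[2]}:a={spacing:g}",
        is_chain=False,
    )


def generate_ideal_chain(
    n: int, bond_length: float = RESIDUE_SIZE, seed: int = 0
) -> CoordinateChain:
    """Freely-jointed random walk: fixed bond length, no excluded volume.

    Each bond direction is drawn independently and uniformly on the sphere,
    so <R^2> = (n - 1) b^2.  Output is fully determined by (n, bond_length,
    seed).
    """
    if n < 2:
        raise ValueError("chain needs at least 2 points")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(steps * bond_length, axis=0)])
    return CoordinateChain(
        points=pts,
        source_id=f"ideal_chain:n={n}:b={bond_length:g}:seed={seed}",
        is_chain=True,
    )


def size_ladder(n_min: int = 64, n_max: int = 4096, factor: float = 2.0) -> list[int]:
    """Geometric grid of sizes for scaling runs."""
    sizes, n = [], float(n_min)
    while round(n) <= n_max:
        sizes.append(int(round(n)))
        n *= factor
    return sizes


def spawn_seeds(master_seed: int, count: int) -> list[int]:
    """Derive ``count`` reproducible sub-seeds (each < 2^31) from one seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(count) % (2**31)]
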