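"""Coordinate input/output and geometric descriptors.

A structure is reduced to one point per residue (its C-alpha atom) or one
point per lattice/polymer site.  Geometric descriptors derived here are the
radius of gyration and the shape factor

    s = N a^3 / (L1 L2 L3),

the residue packing density inside the inertia ellipsoid, where a = 3.8 A is
the residue size and L1 >= L2 >= L3 are the principal semi-axes of the
equivalent uniform ellipsoid (L_i = sqrt(5 mu_i) with mu_i the gyration-tensor
eigenvalues).  Compact single-domain proteins have s around 1-2; elongated or
loosely linked multi-domain structures fall well below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

import gemmi

RESIDUE_SIZE = 3.8  # virtual C-alpha bond length, Angstrom


@dataclass
class CoordinateChain:
    """An ordered set of 3D points (Angstrom) with identity metadata.

    ``is_chain`` is True when sequential order corresponds to a covalent
    backbone (protein chains, generated polymers) and False for lattice
    clusters.
    """

    points: np.ndarray
    labels: list = field(default_factory=list)
    source_id: str = ""
    is_chain: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if not self.labels:
            self.labels = list(range(1, len(self.points) + 1))
        if self.is_chain and len(self.points) >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(steps <= 0):
                raise ValueError("consecutive points of a chain must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ShapeDescriptor:
    """Radius of gyration, principal semi-axes and shape factor."""

    rg: float
    axes: tuple[float, float, float]  # L1 >= L2 >= L3, Angstrom
    s: float
    a: float = RESIDUE_SIZE


def parse_structure(pdb_text: str, chain_id: str, model_index: int = 0) -> CoordinateChain:
    """Extract the C-alpha trace of one chain from PDB-format text.

    One point per residue, in residue order.  Alternate locations are
    resolved to the highest-occupancy conformer (ties go to altloc 'A');
    HETATM records are ignored.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models found in PDB text")
    if model_index >= len(structure):
        raise ValueError(f"model index {model_index} out of range ({len(structure)} models)")
    model = structure[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(c.name for c in model) or "(none)"
        raise ValueError(f"chain {chain_id!r} not found; available chains: {available}")

    points, labels = [], []
    for residue in chain:
        if residue.het_flag != "A":  # skip HETATM (waters, ligands, modified hets)
            continue
        cas = [a for a in residue if a.name == "CA"]
        if not cas:
            continue
        # highest occupancy wins; altloc '' or 'A' preferred on ties
        ca = min(cas, key=lambda a: (-a.occ, a.altloc or "A"))
        points.append([ca.pos.x, ca.pos.y, ca.pos.z])
        labels.append(f"{residue.seqid.num}{residue.seqid.icode}".strip())
    if len(points) < 2:
        raise ValueError(
            f"chain {chain_id!r} has {len(points)} C-alpha atoms; need at least 2"
        )
    return CoordinateChain(
        points=np.array(points),
        labels=labels,
        source_id=f"{(structure.name or 'structure').lower()}:{chain_id}",
        is_chain=True,
    )


def write_pdb(chain: CoordinateChain, chain_id: str = "A") -> str:
    """Render a chain as fixed-column PDB ATOM records (CA trace)."""
    lines = []
    for i, (p, label) in enumerate(zip(chain.points, chain.labels), start=1):
        try:
            resseq = int(str(label))
        except ValueError:
            resseq = i
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain_id}{resseq:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_xyz(chain: CoordinateChain) -> str:
    """Whitespace-delimited table, one point per line: index x y z."""
    rows = [
        f"{i} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
        for i, p in enumerate(chain.points, start=1)
    ]
    return "\n".join(rows) + "\n"


def read_xyz(text: str, source_id: str = "xyz", is_chain: bool = False) -> CoordinateChain:
    pts, labels = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed xyz line: {line!r}")
        labels.append(parts[0])
        pts.append([float(v) for v in parts[1:]])
    if not pts:
        raise ValueError("empty xyz table")
    return CoordinateChain(np.array(pts), labels=labels, source_id=source_id, is_chain=is_chain)


def radius_of_gyration(chain: CoordinateChain) -> float:
    """Root-mean-square distance of the points from their centroid."""
    pts = chain.points
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def gyration_tensor(chain: CoordinateChain) -> np.ndarray:
    pts = chain.points
    centered = pts - pts.mean(axis=0)
    return centered.T @ centered / len(pts)


def shape_factor(chain: CoordinateChain, a: float = RESIDUE_SIZE) -> ShapeDescriptor:
    """Shape factor s = N a^3 / (L1 L2 L3) from the gyration tensor.

    The semi-axes L_i = sqrt(5 mu_i) are those of the uniform solid ellipsoid
    with the same gyration-tensor eigenvalues mu_1 >= mu_2 >= mu_3.

    Raises
    ------
    ValueError
        for fewer than 4 points or (near-)coplanar point sets, where the
        inertia ellipsoid degenerates.
    """
    n = len(chain)
    if n < 4:
        raise ValueError(f"shape factor needs at least 4 points, got {n}")
    mu = np.linalg.eigvalsh(gyration_tensor(chain))[::-1]  # descending
    if mu[0] <= 0 or mu[2] / mu[0] < 1e-12:
        raise ValueError("degenerate gyration tensor: points are collinear or coplanar")
    axes = tuple(float(math.sqrt(5.0 * m)) for m in mu)
    s = n * a**3 / (axes[0] * axes[1] * axes[2])
    rg = float(math.sqrt(mu.sum()))
    return ShapeDescriptor(rg=rg, axes=axes, s=float(s), a=a)
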