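"""Elastic-network (GNM) construction and normal mode analysis.

The Gaussian network model places a node on every C-alpha (or lattice site)
and a unit-strength spring on every pair closer than a cutoff r_C.  Its
potential is quadratic in the displacements with the Kirchhoff matrix (graph
Laplacian of the contact network) as coupling:

    Gamma_ij = -1            if r_ij <= r_C (i != j)
    Gamma_ii = degree of i

Diagonalizing Gamma gives the normal modes (lambda_i ~ omega_i^2); the
equal-time covariance of residue fluctuations is the Moore-Penrose
pseudoinverse of Gamma (prefactor 3 k_B T / kappa fixed to 1, so all
downstream correlation statistics are scale-free in it).  The symmetric
normalized Laplacian D^-1/2 Gamma D^-1/2 is also provided; its spectrum
lies in [0, 2] and is comparable across system sizes.

A parameter-free variant (pf_gnm) with inverse-square-distance springs on
all pairs and no cutoff is included for comparison; it is known not to
reproduce the protein scaling relations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures_io import CoordinateChain

#: relative tolerance (times lambda_max) below which an eigenvalue counts as zero
ZERO_MODE_RTOL = 1e-9

#: small negative shift for the sparse shift-invert smallest-eigenvalue solve;
#: keeps the factorized matrix nonsingular while leaving the zero mode and
#: lambda_1 well separated in the transformed spectrum
_SHIFT_INVERT_SIGMA = -1e-8


class DisconnectedNetworkError(ValueError):
    """Raised when an operation requires a connected contact network."""


@dataclass
class ContactNetwork:
    """Undirected spring network plus its Kirchhoff (graph Laplacian) matrix."""

    kirchhoff: sp.csr_matrix
    r_cut: float | None
    model: str  # 'gnm_cutoff' | 'pf_gnm'
    source_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Diagonal of Gamma: weighted degree of each node."""
        return np.asarray(self.kirchhoff.diagonal())

    @cached_property
    def edge_array(self) -> np.ndarray:
        """(M, 2) array of unordered node pairs, each edge once."""
        coo = sp.triu(self.kirchhoff, k=1).tocoo()
        return np.stack([coo.row, coo.col], axis=1)

    @property
    def n_edges(self) -> int:
        return len(self.edge_array)

    @cached_property
    def component_labels(self) -> np.ndarray:
        return connected_components(self.kirchhoff, directed=False)[1]

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency matrix (unit weights, no diagonal)."""
        off = -sp.triu(self.kirchhoff, k=1)
        a = (off > 0).astype(float)
        return (a + a.T).tocsr()

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges, weights=None, source_id: str = ""
    ) -> "ContactNetwork":
        """Build a network directly from an edge list (unit springs by default)."""
        pairs = np.asarray(list(edges), dtype=int).reshape(-1, 2)
        w = np.ones(len(pairs)) if weights is None else np.asarray(weights, dtype=float)
        return cls(
            kirchhoff=_kirchhoff_from_edges(n_nodes, pairs, w),
            r_cut=None,
            model="gnm_cutoff",
            source_id=source_id,
        )


@dataclass
class ModeSpectrum:
    """Sorted Laplacian eigenvalues (and optional eigenvectors)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray | None
    n_zero: int
    normalized: bool = False
    complete: bool = True  # False when only the low end of the spectrum was computed

    @property
    def lambda1(self) -> float:
        """Smallest nonzero eigenvalue (after skipping all zero modes)."""
        if self.n_zero >= len(self.eigenvalues):
            raise ValueError("spectrum contains only zero modes")
        return float(self.eigenvalues[self.n_zero])

    @property
    def nonzero(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]


@dataclass(frozen=True)
class CovarianceMatrix:
    """Residue-fluctuation covariance, units of 3 k_B T / kappa = 1."""

    values: np.ndarray
    source_id: str = ""


def build_kirchhoff(
    chain: CoordinateChain, r_cut: float | None = None, model: str = "gnm_cutoff"
) -> ContactNetwork:
    """Kirchhoff matrix of the contact network of a point set.

    ``gnm_cutoff``: unit springs on all pairs with r_ij <= r_cut
    (4 A <= r_cut <= 20 A).  ``pf_gnm``: springs on all pairs with weight
    r_ij^-2, no cutoff.  Emits a warning (with a component report) if the
    resulting network is disconnected.
    """
    pts = chain.points
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if model == "gnm_cutoff":
        if r_cut is None or not (4.0 <= r_cut <= 20.0):
            raise ValueError(f"gnm_cutoff requires r_cut in [4, 20] A, got {r_cut}")
        pairs = cKDTree(pts).query_pairs(r_cut, output_type="ndarray")
        weights = np.ones(len(pairs))
    elif model == "pf_gnm":
        iu = np.triu_indices(n, k=1)
        pairs = np.stack(iu, axis=1)
        d2 = ((pts[iu[0]] - pts[iu[1]]) ** 2).sum(axis=1)
        weights = 1.0 / d2
        r_cut = None
    else:
        raise ValueError(f"unknown model {model!r}")

    gamma = _kirchhoff_from_edges(n, pairs, weights)
    net = ContactNetwork(kirchhoff=gamma, r_cut=r_cut, model=model, source_id=chain.source_id)
    if model == "gnm_cutoff":
        labels = net.component_labels
        n_comp = labels.max() + 1
        if n_comp > 1:
            sizes = np.bincount(labels)
            isolated = int((sizes == 1).sum())
            warnings.warn(
                f"contact network at r_cut={r_cut:g} A is disconnected: "
                f"{n_comp} components (sizes {sorted(sizes.tolist(), reverse=True)[:5]}...), "
                f"{isolated} isolated nodes",
                stacklevel=2,
            )
    return net


def _kirchhoff_from_edges(n: int, pairs: np.ndarray, weights: np.ndarray) -> sp.csr_matrix:
    if len(pairs) == 0:
        return sp.csr_matrix((n, n))
    i, j = pairs[:, 0], pairs[:, 1]
    off = sp.coo_matrix(
        (np.concatenate([-weights, -weights]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    deg = -np.asarray(off.sum(axis=1)).ravel()
    return (off + sp.diags(deg)).tocsr()


def build_lattice_springs(chain: CoordinateChain, shells: int = 2) -> ContactNetwork:
    """Springs to the first ``shells`` neighbour shells of a lattice.

    The cutoff is placed midway between the shell-``shells`` and next-shell
    distances, found by ranking the distinct small pair distances of the
    point set itself (no hard-coded lattice radii).
    """
    if shells not in (1, 2):
        raise ValueError("shells must be 1 or 2")
    pts = chain.points
    tree = cKDTree(pts)
    # nearest-neighbour distance of the point set
    d_nn = np.min(tree.query(pts, k=2)[0][:, 1])
    # distinct distance values up to comfortably past the 3rd shell
    probe = tree.query_pairs(2.05 * d_nn, output_type="ndarray")
    dists = np.linalg.norm(pts[probe[:, 0]] - pts[probe[:, 1]], axis=1)
    uniq = np.unique(np.round(dists / d_nn, 6))
    if len(uniq) <= shells:
        raise ValueError("point set has too few distance shells; not a lattice?")
    r_cut = 0.5 * (uniq[shells - 1] + uniq[shells]) * d_nn
    keep = dists <= r_cut
    gamma = _kirchhoff_from_edges(len(pts), probe[keep], np.ones(int(keep.sum())))
    return ContactNetwork(kirchhoff=gamma, r_cut=float(r_cut), model="gnm_cutoff",
                          source_id=chain.source_id)


def normalized_laplacian(net: ContactNetwork) -> sp.csr_matrix:
    """Symmetric normalized Laplacian L = D^-1/2 Gamma D^-1/2 (unit diagonal)."""
    deg = net.degrees
    zero = np.flatnonzero(deg == 0)
    if len(zero):
        raise ValueError(f"zero-degree nodes {zero.tolist()[:10]} have no normalization")
    inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (inv_sqrt @ net.kirchhoff @ inv_sqrt).tocsr()


def eigenmodes(matrix, n_modes: int | str = "all", normalized: bool = False) -> ModeSpectrum:
    """Ascending eigen-decomposition of a symmetric PSD (sparse) matrix.

    ``n_modes='all'`` computes the dense full spectrum with eigenvectors;
    an integer requests only the lowest ``n_modes`` eigenpairs (sparse
    shift-invert for large systems).  Zero modes are detected with relative
    tolerance ZERO_MODE_RTOL * lambda_max.
    """
    n = matrix.shape[0]
    if n_modes == "all" or (isinstance(n_modes, int) and n_modes >= n) or n <= 64:
        if isinstance(n_modes, int) and n_modes > n:
            raise ValueError(f"requested {n_modes} modes from an {n}-node system")
        dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
        vals, vecs = np.linalg.eigh(dense)
        if isinstance(n_modes, int):
            vals, vecs = vals[:n_modes], vecs[:, :n_modes]
            complete = False
            lam_max = float(np.abs(np.linalg.eigvalsh(dense)).max())
        else:
            complete = True
            lam_max = float(np.abs(vals).max())
    else:
        if n_modes > n:
            raise ValueError(f"requested {n_modes} modes from an {n}-node system")
        k = min(n_modes, n - 1)
        vals, vecs = spla.eigsh(matrix, k=k, sigma=_SHIFT_INVERT_SIGMA, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        complete = False
        lam_max = float(spla.eigsh(matrix, k=1, which="LA", return_eigenvectors=False)[0])
    tol = max(lam_max, 1.0) * ZERO_MODE_RTOL
    n_zero = int(np.sum(np.abs(vals) <= tol))
    vals = vals.copy()
    vals[np.abs(vals) <= tol] = 0.0
    return ModeSpectrum(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero,
                        normalized=normalized, complete=complete)


def slowest_nonzero_eigenvalue(matrix) -> float:
    """lambda_1 of a connected network's (possibly normalized) Laplacian.

    Fast path used by the scaling sweeps: computes only the bottom two
    eigenvalues and returns the nonzero one.
    """
    n = matrix.shape[0]
    if n <= 256 or not sp.issparse(matrix):
        dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
        vals = np.linalg.eigvalsh(dense)
    else:
        vals = np.sort(
            spla.eigsh(matrix, k=2, sigma=_SHIFT_INVERT_SIGMA, which="LM",
                       return_eigenvectors=False)
        )
    tol = max(float(vals[-1]), 1.0) * ZERO_MODE_RTOL
    nonzero = vals[np.abs(vals) > tol]
    if len(nonzero) == 0:
        raise ValueError("no nonzero eigenvalue found")
    return float(nonzero[0])


def covariance_from_network(net: ContactNetwork) -> CovarianceMatrix:
    """Fluctuation covariance C = Gamma^+ (Moore-Penrose pseudoinverse).

    Requires a connected network; the pseudoinverse across disconnected
    components mixes independent zero modes and is not meaningful here.
    """
    if net.n_components > 1:
        raise DisconnectedNetworkError(
            f"network has {net.n_components} components; covariance needs a connected network"
        )
    gamma = net.kirchhoff.toarray()
    n = gamma.shape[0]
    # spectral pseudoinverse: drop the single zero mode
    vals, vecs = np.linalg.eigh(gamma)
    inv = np.zeros_like(vals)
    inv[1:] = 1.0 / vals[1:]
    cov = (vecs * inv) @ vecs.T
    cov = 0.5 * (cov + cov.T)
    assert cov.shape == (n, n)
    return CovarianceMatrix(values=cov, source_id=net.source_id)


def mode_density(spectrum: ModeSpectrum, bin_edges) -> tuple[np.ndarray, np.ndarray]:
    """Histogram g(lambda) of the nonzero eigenvalues, normalized to unit area.

    Returns (density, bin_edges).
    """
    density, edges = np.histogram(spectrum.nonzero, bins=bin_edges, density=True)
    return density, edges
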