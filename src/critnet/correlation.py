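"""Cross-correlations, distance-dependent correlation functions, and
finite-size susceptibility.

From the GNM covariance C the pairwise cross-correlation is

    phi_ij = C_ij / sqrt(C_ii C_jj),

and the distance-dependent correlation function phi(r) is the mean of
phi_ij over residue pairs whose spatial separation falls in the distance
bin at r (half-open bins of configurable width, 1 A by default).  The
correlation length xi is the distance where phi(r) first decays to zero
(linear interpolation between the bracketing bins); the susceptibility

    chi = (s / N) * sum_{i<j, r_ij < xi} phi_ij

is the shape-factor-weighted total correlation within the correlation
length, the finite-size response measure whose growth with N signals
scale-free correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .enm import CovarianceMatrix

DEFAULT_BIN_WIDTH = 1.0  # Angstrom


@dataclass
class CorrelationProfile:
    """Binned phi(r): per-bin mean pair correlation and pair counts.

    Bins are half-open [k*w, (k+1)*w); ``phi`` is NaN where ``counts`` is 0.
    """

    bin_centers: np.ndarray
    phi: np.ndarray
    counts: np.ndarray
    bin_width: float
    rescaled: bool = False  # True when the distance axis is r / Rg

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


class CorrelationLength(NamedTuple):
    value: float
    censored: bool  # True when phi(r) never crosses zero


def cross_correlation(cov: CovarianceMatrix | np.ndarray) -> np.ndarray:
    """Normalize a covariance matrix to unit diagonal."""
    c = cov.values if isinstance(cov, CovarianceMatrix) else np.asarray(cov)
    diag = np.diag(c)
    bad = np.flatnonzero(diag <= 0)
    if len(bad):
        raise ValueError(f"non-positive covariance diagonal at nodes {bad.tolist()[:10]}")
    scale = 1.0 / np.sqrt(diag)
    phi = c * scale[:, None] * scale[None, :]
    return np.clip(phi, -1.0, 1.0)


def pair_distances(points: np.ndarray) -> np.ndarray:
    """Full symmetric pairwise distance matrix (Angstrom)."""
    return squareform(pdist(np.asarray(points, dtype=float)))


def correlation_function(
    phi_matrix: np.ndarray,
    distances: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> CorrelationProfile:
    """phi(r): mean of phi_ij over unordered pairs binned by distance.

    A pair lying exactly on a bin edge belongs to the upper bin (half-open
    binning).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    phi_matrix = np.asarray(phi_matrix)
    distances = np.asarray(distances)
    if phi_matrix.shape != distances.shape:
        raise ValueError("phi matrix and distance matrix shapes differ")
    iu = np.triu_indices(phi_matrix.shape[0], k=1)
    r = distances[iu]
    phi = phi_matrix[iu]
    idx = np.floor(r / bin_width).astype(int)
    n_bins = int(idx.max()) + 1 if len(idx) else 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=phi, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return CorrelationProfile(
        bin_centers=centers, phi=mean, counts=counts, bin_width=bin_width
    )


def correlation_length(profile: CorrelationProfile) -> CorrelationLength:
    """First zero crossing of phi(r), linearly interpolated.

    Scans occupied bins in distance order; at the first transition from a
    positive bin to a non-positive bin, interpolates the crossing distance.
    If phi stays positive over all occupied bins the result is censored at
    the last occupied bin center.
    """
    occ = np.flatnonzero(profile.occupied)
    if len(occ) < 2:
        raise ValueError("profile needs at least 2 occupied bins")
    x = profile.bin_centers[occ]
    y = profile.phi[occ]
    for k in range(1, len(occ)):
        if y[k] <= 0 and y[k - 1] > 0:
            frac = y[k - 1] / (y[k - 1] - y[k])
            return CorrelationLength(float(x[k - 1] + frac * (x[k] - x[k - 1])), False)
    return CorrelationLength(float(x[-1]), True)


def susceptibility(
    phi_matrix: np.ndarray,
    distances: np.ndarray,
    xi: float,
    s: float,
    n: int,
) -> float:
    """chi = (s/N) * sum of phi_ij over unordered pairs with r_ij < xi.

    The Heaviside cut is strict: pairs at exactly r_ij = xi are excluded.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    if s <= 0:
        raise ValueError("shape factor must be positive")
    iu = np.triu_indices(np.asarray(phi_matrix).shape[0], k=1)
    mask = np.asarray(distances)[iu] < xi
    return float(s / n * np.asarray(phi_matrix)[iu][mask].sum())


def group_average(
    profiles: Sequence[CorrelationProfile],
    rg_values: Sequence[float],
    rg_bin_center: float,
    window_half_width: float = 0.5,
) -> CorrelationProfile:
    """Average phi(r) over structures in one Rg window.

    The window is half-open: [center - w, center + w).  Each structure
    contributes with equal weight; distance bins are averaged over the
    member profiles that have a value there.
    """
    if len(profiles) != len(rg_values):
        raise ValueError("profiles and rg_values lengths differ")
    lo = rg_bin_center - window_half_width
    hi = rg_bin_center + window_half_width
    members = [p for p, rg in zip(profiles, rg_values) if lo <= rg < hi]
    if not members:
        rgs = np.asarray(rg_values, dtype=float)
        raise ValueError(
            f"no structures with Rg in [{lo:g}, {hi:g}); "
            f"available Rg range {rgs.min():g}-{rgs.max():g} A"
        )
    widths = {p.bin_width for p in members}
    if len(widths) != 1:
        raise ValueError("member profiles use different bin widths")
    rescales = {p.rescaled for p in members}
    if len(rescales) != 1:
        raise ValueError("cannot mix rescaled and unrescaled profiles")
    n_bins = max(len(p.bin_centers) for p in members)
    acc = np.zeros(n_bins)
    nvals = np.zeros(n_bins, dtype=int)
    counts = np.zeros(n_bins, dtype=int)
    for p in members:
        k = len(p.bin_centers)
        good = p.occupied
        acc[:k][good] += p.phi[good]
        nvals[:k][good] += 1
        counts[:k] += p.counts
    with np.errstate(invalid="ignore"):
        mean = np.where(nvals > 0, acc / np.maximum(nvals, 1), np.nan)
    width = members[0].bin_width
    return CorrelationProfile(
        bin_centers=(np.arange(n_bins) + 0.5) * width,
        phi=mean,
        counts=counts,
        bin_width=width,
        rescaled=members[0].rescaled,
    )


def rescale_profile(profile: CorrelationProfile, rg: float) -> CorrelationProfile:
    """Express the distance axis in units of Rg (for size-collapse plots)."""
    if rg <= 0:
        raise ValueError("rg must be positive")
    return replace(
        profile,
        bin_centers=profile.bin_centers / rg,
        bin_width=profile.bin_width / rg,
        rescaled=True,
    )
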