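"""Power-law fitting and size-binning for finite-size scaling analysis.

All scaling relations analysed here are straight lines on log-log axes, so
exponents come from ordinary least squares on (log10 x, log10 y).  The
modularity law Q = 1 - K N^(-eta) is fitted after the inversion 1 - Q, and
the effective dimension implied by eta = 1/(d+1) is d_eff = 1/eta - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 y on log10 x.

    ``exponent`` is the raw slope unless the caller applies a sign
    convention: decays such as lambda_1 ~ N^-zeta are stored negated
    (zeta > 0), growth laws like <l> ~ N^alpha keep the raw slope.
    """

    exponent: float
    prefactor: float
    stderr_exponent: float
    r_squared: float
    n_points: int

    def negated(self) -> "PowerLawFit":
        return PowerLawFit(
            exponent=-self.exponent,
            prefactor=self.prefactor,
            stderr_exponent=self.stderr_exponent,
            r_squared=self.r_squared,
            n_points=self.n_points,
        )


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit y = prefactor * x^exponent by least squares in log-log space."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if len(bad):
        raise ValueError(
            f"non-positive or non-finite values at indices {bad.tolist()[:10]}"
        )
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(10.0**res.intercept),
        stderr_exponent=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def fit_modularity_scaling(n_values: Sequence[float], q_values: Sequence[float]) -> PowerLawFit:
    """Fit Q = 1 - K N^(-eta); returns eta (> 0) as exponent and K as prefactor."""
    q = np.asarray(q_values, dtype=float)
    if np.any(q >= 1):
        raise ValueError("modularity values must be < 1 for the 1 - Q inversion")
    return fit_power_law(n_values, 1.0 - q).negated()


def effective_dimension(eta: float) -> float:
    """Invert the modularity-scaling law eta = 1/(d+1): d_eff = 1/eta - 1."""
    if not (0.0 < eta < 1.0):
        raise ValueError(f"eta must lie in (0, 1), got {eta}")
    return 1.0 / eta - 1.0


def bin_by_size(
    records: pd.DataFrame,
    key: str,
    value: str,
    bin_width: float | None = None,
    bin_edges: Sequence[float] | None = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Half-open binned means of one descriptor column.

    ``key`` is the size variable ('N' or 'rg'); bins come either from a
    uniform ``bin_width`` starting at 0 or from explicit ``bin_edges``.
    Bins with fewer than ``min_count`` members are flagged (column
    ``sparse``), not dropped.
    """
    if (bin_width is None) == (bin_edges is None):
        raise ValueError("give exactly one of bin_width or bin_edges")
    x = records[key].to_numpy(dtype=float)
    y = records[value].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if bin_width is not None:
        idx = np.floor(x / bin_width).astype(int)
        centers_of = lambda k: (k + 0.5) * bin_width
    else:
        edges = np.asarray(bin_edges, dtype=float)
        idx = np.searchsorted(edges, x, side="right") - 1
        inside = (idx >= 0) & (idx < len(edges) - 1)
        x, y, idx = x[inside], y[inside], idx[inside]
        centers_of = lambda k: 0.5 * (edges[k] + edges[k + 1])
    out = []
    for k in np.unique(idx):
        sel = idx == k
        out.append(
            {
                "bin_center": float(centers_of(k)),
                "mean": float(y[sel].mean()),
                "count": int(sel.sum()),
            }
        )
    df = pd.DataFrame(out)
    df["sparse"] = df["count"] < min_count
    return df
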