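"""End-to-end orchestration: structures in, descriptor table and scaling fits out.

``run_structure`` composes the full per-structure analysis (geometry, GNM
spectra at two cutoffs, correlation statistics, network topology) into one
ScalingRecord row; ``run_dataset`` maps it over many inputs and fits the
scaling laws.  The ``*_scaling`` suite functions reproduce the
reference-system scaling analyses (fcc / cubic lattices, ideal polymer
ensembles) without any external input.

Two cutoffs are carried through every run: r_cut_corr (9 A) for mode and
correlation analysis and r_cut_topo (8 A) for topology descriptors, so one
pass yields both families of results.

Spectrum conventions for reported slow modes: a record carries both
``lambda1`` (smallest nonzero eigenvalue of the symmetric normalized
Laplacian) and ``lambda1_raw`` (raw Kirchhoff).  The lattice scaling suite
fits the normalized eigenvalue, whose finite-cluster exponent is free of the
surface-degree transient; the polymer suite fits the raw GNM eigenvalue,
because for chain ensembles the mean contact degree itself drifts with N
over desk-scale sizes and degree normalization distorts the exponent.  See
docs/methods.md for the measurements behind this choice.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import correlation as corr
from . import enm, scaling, topology
from .reference_systems import (
    GeneratorSpec,
    generate_cubic_lattice,
    generate_fcc_cluster,
    generate_ideal_chain,
    spawn_seeds,
)
from .structures_io import CoordinateChain, parse_structure, radius_of_gyration, shape_factor

DEFAULT_POLYMER_SIZES = (64, 128, 256, 512, 1024, 2048)
DEFAULT_FCC_MODE_SIZES = (64, 128, 256, 512, 1024, 2048, 4096)
DEFAULT_FCC_MODULARITY_SIZES = (100, 200, 400, 800, 1600, 3200, 5000)
DEFAULT_CUBIC_DIMS = (4, 5, 6, 7, 8, 10, 12)


@dataclass
class AnalysisConfig:
    """Declarative run configuration (all knobs of the per-structure pass)."""

    r_cut_corr: float = 9.0   # A, modes + correlation statistics
    r_cut_topo: float = 8.0   # A, path length + modularity
    bin_width: float = 1.0    # A, phi(r) binning
    louvain_restarts: int = 10
    seed: int = 0
    min_chain_len: int = 30   # dataset filter, applied to parsed structures only
    max_chain_len: int = 1200
    residue_size: float = 3.8  # A

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self))

    @classmethod
    def from_text(cls, text: str) -> "AnalysisConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            caster = int if types[key] == "int" else float
            kwargs[key] = caster(value.strip())
        return cls(**kwargs)


@dataclass
class ScalingRecord:
    """One row of the per-structure descriptor table."""

    source_id: str
    n: int
    rg: float | None = None
    s: float | None = None
    lambda1: float | None = None        # normalized Laplacian, r_cut_corr
    lambda1_raw: float | None = None    # raw Kirchhoff, r_cut_corr
    mean_path: float | None = None      # r_cut_topo
    q: float | None = None              # Louvain-maximized modularity, r_cut_topo
    n_communities: int | None = None
    xi: float | None = None             # A
    censored_xi: bool | None = None
    chi: float | None = None
    r_cut_corr: float = 9.0
    r_cut_topo: float = 8.0
    reasons: dict = field(default_factory=dict)  # field -> why it is null

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reasons"] = ";".join(f"{k}:{v}" for k, v in self.reasons.items())
        return d


def _load_input(item, config: AnalysisConfig) -> CoordinateChain:
    if isinstance(item, CoordinateChain):
        return item
    if isinstance(item, GeneratorSpec):
        return item.build()
    path = Path(item)
    text = path.read_text()
    if path.suffix in (".xyz", ".txt", ".dat"):
        from .structures_io import read_xyz

        return read_xyz(text, source_id=path.stem)
    # default: PDB, first protein chain unless encoded as "file.pdb:B"
    return parse_structure(text, chain_id=_first_chain_id(text), model_index=0)


def _first_chain_id(pdb_text: str) -> str:
    for line in pdb_text.splitlines():
        if line.startswith("ATOM"):
            return line[21].strip() or "A"
    raise ValueError("no ATOM records found")


def run_structure(item, config: AnalysisConfig | None = None) -> ScalingRecord:
    """Full per-structure analysis; partial failures null the affected fields.

    The input may be a CoordinateChain, a GeneratorSpec, or a path to a
    PDB / xyz file.
    """
    config = config or AnalysisConfig()
    chain = _load_input(item, config)
    rec = ScalingRecord(
        source_id=chain.source_id,
        n=len(chain),
        r_cut_corr=config.r_cut_corr,
        r_cut_topo=config.r_cut_topo,
    )
    rec.rg = radius_of_gyration(chain)
    try:
        rec.s = shape_factor(chain, a=config.residue_size).s
    except ValueError as exc:
        rec.reasons["s"] = str(exc)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net_corr = enm.build_kirchhoff(chain, r_cut=config.r_cut_corr)
        net_topo = enm.build_kirchhoff(chain, r_cut=config.r_cut_topo)

    if net_corr.n_components == 1:
        rec.lambda1 = enm.slowest_nonzero_eigenvalue(enm.normalized_laplacian(net_corr))
        rec.lambda1_raw = enm.slowest_nonzero_eigenvalue(net_corr.kirchhoff)
        try:
            cov = enm.covariance_from_network(net_corr)
            phi = corr.cross_correlation(cov)
            dist = corr.pair_distances(chain.points)
            profile = corr.correlation_function(phi, dist, bin_width=config.bin_width)
            xi = corr.correlation_length(profile)
            rec.xi, rec.censored_xi = xi.value, xi.censored
            if rec.s is not None:
                rec.chi = corr.susceptibility(phi, dist, xi.value, rec.s, len(chain))
            else:
                rec.reasons["chi"] = "no shape factor"
        except ValueError as exc:
            rec.reasons["xi"] = rec.reasons["chi"] = str(exc)
    else:
        rec.reasons["lambda1"] = rec.reasons["xi"] = rec.reasons["chi"] = "disconnected"

    if net_topo.n_components == 1:
        rec.mean_path = topology.average_path_length(net_topo, seed=config.seed)
        part = topology.best_partition(
            net_topo, n_restarts=config.louvain_restarts, seed=config.seed
        )
        rec.q, rec.n_communities = part.q, part.n_communities
    else:
        rec.reasons["mean_path"] = rec.reasons["q"] = "disconnected"
    return rec


def run_dataset(
    items: Iterable, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Analyze many inputs; returns the record table and scaling-fit report.

    Parsed structures outside the chain-length window
    [min_chain_len, max_chain_len] are skipped (logged in the report);
    generated reference systems are never length-filtered.
    """
    config = config or AnalysisConfig()
    items = list(items)
    if not items:
        raise ValueError("empty input list")
    rows, skipped, failures = [], [], []
    for item in items:
        is_file = not isinstance(item, (CoordinateChain, GeneratorSpec))
        try:
            chain = _load_input(item, config)
        except (ValueError, OSError) as exc:
            failures.append({"item": str(item), "error": str(exc)})
            continue
        if is_file and not (config.min_chain_len <= len(chain) <= config.max_chain_len):
            skipped.append({"item": str(item), "n": len(chain), "reason": "chain length filter"})
            continue
        rows.append(run_structure(chain, config).as_dict())
    if not rows:
        raise RuntimeError(f"all {len(items)} inputs failed or were skipped: {failures or skipped}")
    table = pd.DataFrame(rows)
    report = {"skipped": skipped, "failures": failures, "fits": fit_scaling_report(table)}
    return table, report


def fit_scaling_report(table: pd.DataFrame) -> dict:
    """Power-law fits of the standard descriptor/size relations.

    lambda1, <l> and 1-Q are fitted against N on per-size means (log-mean
    for lambda1); xi is fitted against Rg on the uncensored rows.  Fits
    with fewer than 3 distinct sizes are skipped.
    """
    fits: dict[str, scaling.PowerLawFit] = {}
    sized = table.dropna(subset=["n"])

    def per_size(col: str, log_mean: bool = False) -> tuple[np.ndarray, np.ndarray] | None:
        sub = sized.dropna(subset=[col])
        if sub.empty or sub["n"].nunique() < 3:
            return None
        grouped = (
            sub.groupby("n")[col].apply(lambda v: float(np.exp(np.log(v).mean())))
            if log_mean
            else sub.groupby("n")[col].mean()
        )
        return grouped.index.to_numpy(float), grouped.to_numpy(float)

    xy = per_size("lambda1", log_mean=True)
    if xy:
        fits["zeta"] = scaling.fit_power_law(*xy).negated()
    xy = per_size("lambda1_raw", log_mean=True)
    if xy:
        fits["zeta_raw"] = scaling.fit_power_law(*xy).negated()
    xy = per_size("mean_path")
    if xy:
        fits["alpha"] = scaling.fit_power_law(*xy)
    sub = sized.dropna(subset=["q"])
    if not sub.empty and sub["n"].nunique() >= 3:
        grouped = sub.groupby("n")["q"].mean()
        fits["eta"] = scaling.fit_modularity_scaling(
            grouped.index.to_numpy(float), grouped.to_numpy(float)
        )
    sub = table.dropna(subset=["xi", "rg"])
    sub = sub[sub["censored_xi"] == False]  # noqa: E712 — pandas boolean column
    if len(sub) >= 3:
        fits["xi_vs_rg"] = scaling.fit_power_law(
            sub["rg"].to_numpy(float), sub["xi"].to_numpy(float)
        )
    xy_chi = sized.dropna(subset=["chi"])
    if not xy_chi.empty and xy_chi["n"].nunique() >= 3 and (xy_chi["chi"] > 0).all():
        grouped = xy_chi.groupby("n")["chi"].mean()
        fits["chi_exponent"] = scaling.fit_power_law(
            grouped.index.to_numpy(float), grouped.to_numpy(float)
        )
    return fits


# ---------------------------------------------------------------------------
# Reference-system scaling suites (self-contained, no external input)
# ---------------------------------------------------------------------------


def fcc_mode_scaling(
    sizes: Sequence[int] = DEFAULT_FCC_MODE_SIZES, spacing: float = 3.8
) -> scaling.PowerLawFit:
    """zeta of fcc clusters: normalized-Laplacian lambda_1 ~ N^-zeta.

    Springs connect first and second neighbour shells; clusters are carved
    near-spherical.  Deterministic.
    """
    lam = []
    for n in sizes:
        net = enm.build_lattice_springs(generate_fcc_cluster(n, spacing), shells=2)
        lam.append(enm.slowest_nonzero_eigenvalue(enm.normalized_laplacian(net)))
    return scaling.fit_power_law(np.asarray(sizes, float), np.asarray(lam)).negated()


def fcc_path_scaling(
    sizes: Sequence[int] = DEFAULT_FCC_MODE_SIZES, spacing: float = 3.8, seed: int = 0
) -> scaling.PowerLawFit:
    """alpha of fcc clusters: <l> ~ N^alpha on the shells-2 contact network."""
    vals = []
    for n in sizes:
        net = enm.build_lattice_springs(generate_fcc_cluster(n, spacing), shells=2)
        vals.append(topology.average_path_length(net, seed=seed))
    return scaling.fit_power_law(np.asarray(sizes, float), np.asarray(vals))


def fcc_modularity_scaling(
    sizes: Sequence[int] = DEFAULT_FCC_MODULARITY_SIZES,
    spacing: float = 3.8,
    seed: int = 0,
    n_restarts: int = 10,
) -> scaling.PowerLawFit:
    """eta of fcc clusters from Q = 1 - K N^-eta with Louvain best-of-restarts."""
    qs = []
    for n in sizes:
        net = enm.build_lattice_springs(generate_fcc_cluster(n, spacing), shells=2)
        qs.append(topology.best_partition(net, n_restarts=n_restarts, seed=seed).q)
    return scaling.fit_modularity_scaling(np.asarray(sizes, float), np.asarray(qs))


def cubic_modularity_scaling(
    dims: Sequence[int] = DEFAULT_CUBIC_DIMS,
    spacing: float = 3.8,
    seed: int = 0,
    n_restarts: int = 10,
) -> scaling.PowerLawFit:
    """eta of full cubic lattices (nearest-neighbour springs)."""
    sizes, qs = [], []
    for d in dims:
        net = enm.build_lattice_springs(generate_cubic_lattice((d, d, d), spacing), shells=1)
        sizes.append(d**3)
        qs.append(topology.best_partition(net, n_restarts=n_restarts, seed=seed).q)
    return scaling.fit_modularity_scaling(np.asarray(sizes, float), np.asarray(qs))


def polymer_reference_table(
    sizes: Sequence[int] = DEFAULT_POLYMER_SIZES,
    seeds_per_size: int = 20,
    master_seed: int = 0,
    bond_length: float = 3.8,
    r_cut_modes: float = 9.0,
    r_cut_topo: float = 8.0,
    louvain_restarts: int = 10,
) -> pd.DataFrame:
    """Slow modes and topology descriptors of a freely-jointed chain ensemble.

    One row per (size, replicate): lambda1_raw and lambda1 (normalized) at
    ``r_cut_modes``, mean shortest-path length and Louvain modularity at
    ``r_cut_topo``.  All randomness derives from ``master_seed``.
    """
    chain_seeds = spawn_seeds(master_seed, len(sizes) * seeds_per_size)
    aux_seeds = spawn_seeds(master_seed + 1, len(sizes) * seeds_per_size)
    rows = []
    k = 0
    for n in sizes:
        for _ in range(seeds_per_size):
            chain = generate_ideal_chain(n, bond_length=bond_length, seed=chain_seeds[k])
            net_m = enm.build_kirchhoff(chain, r_cut=r_cut_modes)
            net_t = enm.build_kirchhoff(chain, r_cut=r_cut_topo)
            part = topology.best_partition(net_t, n_restarts=louvain_restarts, seed=aux_seeds[k])
            rows.append(
                {
                    "n": n,
                    "seed": chain_seeds[k],
                    "lambda1_raw": enm.slowest_nonzero_eigenvalue(net_m.kirchhoff),
                    "lambda1": enm.slowest_nonzero_eigenvalue(enm.normalized_laplacian(net_m)),
                    "mean_path": topology.average_path_length(net_t, seed=aux_seeds[k]),
                    "q": part.q,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def polymer_mode_scaling(table: pd.DataFrame) -> scaling.PowerLawFit:
    """zeta of the polymer ensemble from the raw GNM spectrum.

    Per-size aggregation is the log-mean: lambda_1 of a chain ensemble at
    fixed N spans decades, so the geometric mean is the location parameter
    consistent with fitting a line through the log-log scatter.
    """
    g = table.groupby("n")["lambda1_raw"].apply(lambda v: float(np.exp(np.log(v).mean())))
    return scaling.fit_power_law(g.index.to_numpy(float), g.to_numpy(float)).negated()


def polymer_path_scaling(table: pd.DataFrame) -> scaling.PowerLawFit:
    """alpha of the polymer ensemble (arithmetic per-size means of <l>)."""
    g = table.groupby("n")["mean_path"].mean()
    return scaling.fit_power_law(g.index.to_numpy(float), g.to_numpy(float))


def polymer_modularity_scaling(table: pd.DataFrame) -> scaling.PowerLawFit:
    """eta of the polymer ensemble (arithmetic per-size means of 1 - Q)."""
    g = table.groupby("n")["q"].mean()
    return scaling.fit_modularity_scaling(g.index.to_numpy(float), g.to_numpy(float))
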