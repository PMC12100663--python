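"""Synthetic administrative hierarchies and space-time rate panels.

The generator produces a nested hierarchy on a rectangular lattice and a
strictly positive rate panel whose log-scale decomposition (national
temporal trend, rural/urban, region, province, city, county, residual)
has *exactly* known component variances: every effect vector is drawn
from its structural prior (random-walk path for the trend, intrinsic CAR
draw for the county surface, iid normals elsewhere), centered, and then
rescaled so that its empirical variance — pooled over the panel cells it
replicates into — equals its target share of the total log variance.
That makes downstream parameter-recovery tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AdminHierarchy, LatticeGeometry, SpaceTimePanel
from .weights import SpatialWeights

__all__ = [
    "COMPONENTS",
    "SimulationTruth",
    "make_hierarchy",
    "simulate_panel",
]

#: canonical component order: trend, rural/urban, region, province, city,
#: county, residual
COMPONENTS = ("psi", "omega", "delta", "phi", "gamma", "xi", "residual")

DEFAULT_ALPHA = float(np.log(50.0))  # median rate ~ 50 per 100,000


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth effects behind a simulated panel."""

    alpha: float
    psi_true: np.ndarray
    omega_true: np.ndarray
    delta_true: np.ndarray
    phi_true: np.ndarray
    gamma_true: np.ndarray
    xi_true: np.ndarray
    target_shares: np.ndarray
    total_variance: float
    seed: int

    def component_vector(self, name: str) -> np.ndarray:
        return {
            "psi": self.psi_true,
            "omega": self.omega_true,
            "delta": self.delta_true,
            "phi": self.phi_true,
            "gamma": self.gamma_true,
            "xi": self.xi_true,
        }[name]


def make_hierarchy(
    n_regions: int,
    provinces_per_region: int,
    cities_per_province: int,
    counties_per_city: int,
    urban_fraction: float,
    seed: int,
) -> tuple[AdminHierarchy, LatticeGeometry]:
    """Balanced nested hierarchy on a gap-free rectangular lattice.

    Each province occupies one full grid row; its cities are consecutive
    segments of that row; regions are consecutive row blocks.  Every
    administrative unit is therefore spatially compact under rook
    contiguity.  Urban flags are a seeded Bernoulli draw; when the
    fraction is strictly between 0 and 1 and there are ≥ 2 counties, at
    least one county of each kind is forced so both levels exist.
    """
    counts = (n_regions, provinces_per_region, cities_per_province, counties_per_city)
    if any(int(c) != c or c < 1 for c in counts):
        raise ValueError("all counts must be positive integers")
    if not 0.0 <= urban_fraction <= 1.0:
        raise ValueError("urban_fraction must be in [0, 1]")
    n_rows = n_regions * provinces_per_region
    n_cols = cities_per_province * counties_per_city
    n_counties = n_rows * n_cols

    county_ids, coords = [], {}
    city_of, province_of, region_of, urban = {}, {}, {}, {}
    k = 0
    for r in range(n_regions):
        region = f"R{r + 1}"
        for p in range(provinces_per_region):
            province = f"{region}-P{p + 1}"
            region_of[province] = region
            row = r * provinces_per_region + p
            for c in range(cities_per_province):
                city = f"{province}-C{c + 1}"
                province_of[city] = province
                for m in range(counties_per_city):
                    county = f"cnty{k + 1:05d}"
                    col = c * counties_per_city + m
                    county_ids.append(county)
                    coords[county] = (row, col)
                    city_of[county] = city
                    k += 1

    rng = np.random.default_rng(seed)
    flags = rng.random(n_counties) < urban_fraction
    if n_counties > 1 and 0.0 < urban_fraction < 1.0:
        if not flags.any():
            flags[rng.integers(n_counties)] = True
        if flags.all():
            flags[rng.integers(n_counties)] = False
    urban = dict(zip(county_ids, (bool(f) for f in flags)))

    hierarchy = AdminHierarchy(
        tuple(county_ids), city_of, province_of, region_of, urban
    )
    return hierarchy, LatticeGeometry(coords)


def _pooled_variance(values: np.ndarray, cell_counts: np.ndarray) -> float:
    """Variance of ``values`` replicated ``cell_counts`` times each."""
    w = cell_counts / cell_counts.sum()
    mu = float(w @ values)
    return float(w @ (values - mu) ** 2)


def _center_rescale(
    vec: np.ndarray, cell_counts: np.ndarray, target_var: float, what: str
) -> np.ndarray:
    """Zero-mean vector whose cell-pooled empirical variance is exact."""
    if target_var == 0.0:
        return np.zeros_like(vec)
    vec = vec - vec.mean()
    pv = _pooled_variance(vec, cell_counts)
    if pv <= 0.0:
        raise ValueError(
            f"cannot realize positive variance for component {what!r}: "
            "degenerate draw (too few distinct groups?)"
        )
    return vec * np.sqrt(target_var / pv)


def _icar_draw(weights: SpatialWeights, rng: np.random.Generator) -> np.ndarray:
    """Intrinsic-CAR sample: eigen-decomposition of the graph Laplacian
    restricted to the non-null space (one null vector per connected
    component), which makes the draw mean-zero per component."""
    lap = weights.laplacian().toarray()
    lam, vecs = np.linalg.eigh(lap)
    keep = lam > 1e-9
    if not keep.any():
        raise ValueError("county adjacency has no edges; iCAR draw undefined")
    z = rng.standard_normal(int(keep.sum())) / np.sqrt(lam[keep])
    return vecs[:, keep] @ z


def simulate_panel(
    hierarchy: AdminHierarchy,
    weights: SpatialWeights,
    n_years: int,
    target_shares,
    alpha: float = DEFAULT_ALPHA,
    total_variance: float = 1.0,
    seed: int = 0,
    first_year: int = 1996,
) -> tuple[SpaceTimePanel, SimulationTruth]:
    """Generate a strictly positive rate panel with known variance shares.

    ``target_shares`` is a length-7 sequence (or mapping keyed by
    ``COMPONENTS``) of nonnegative proportions summing to 1, ordered as
    trend / rural-urban / region / province / city / county / residual.
    """
    if isinstance(target_shares, dict):
        shares = np.array([target_shares[c] for c in COMPONENTS], dtype=float)
    else:
        shares = np.asarray(target_shares, dtype=float)
    if shares.shape != (7,):
        raise ValueError("target_shares must have exactly 7 entries")
    if (shares < 0).any():
        raise ValueError("target_shares must be nonnegative")
    if abs(shares.sum() - 1.0) > 1e-12:
        raise ValueError(f"target_shares must sum to 1, got {shares.sum()!r}")
    if n_years < 2 and shares[0] > 0:
        raise ValueError("temporal share > 0 requires n_years >= 2")
    if tuple(weights.ids) != tuple(hierarchy.county_ids):
        raise ValueError("weights must be defined on the hierarchy's counties")
    if shares[5] > 0 and weights.n_edges == 0:
        raise ValueError("county share > 0 requires a non-empty adjacency")
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")

    rng = np.random.default_rng(seed)
    K, T = hierarchy.n_counties, int(n_years)
    tv = shares * total_variance

    u_idx, _ = hierarchy.group_indices("rural-urban")
    s_idx, _ = hierarchy.group_indices("region")
    p_idx, _ = hierarchy.group_indices("province")
    c_idx, _ = hierarchy.group_indices("city")

    # trend: RW1 path, pooled over K counties per year (equal weights)
    if tv[0] > 0:
        path = np.cumsum(rng.standard_normal(T))
        psi = _center_rescale(path, np.full(T, K), tv[0], "psi")
    else:
        psi = np.zeros(T)

    def iid_level(idx: np.ndarray, n_groups: int, var: float, what: str):
        if var == 0.0:
            return np.zeros(n_groups)
        counts = np.bincount(idx, minlength=n_groups) * T
        draw = rng.standard_normal(n_groups)
        return _center_rescale(draw, counts, var, what)

    omega = iid_level(u_idx, 2, tv[1], "omega")
    delta = iid_level(s_idx, len(hierarchy.regions), tv[2], "delta")
    phi = iid_level(p_idx, len(hierarchy.provinces), tv[3], "phi")
    gamma = iid_level(c_idx, len(hierarchy.cities), tv[4], "gamma")

    if tv[5] > 0:
        xi = _center_rescale(_icar_draw(weights, rng), np.full(K, T), tv[5], "xi")
    else:
        xi = np.zeros(K)

    if tv[6] > 0:
        eps = rng.standard_normal((K, T))
        eps = eps - eps.mean()
        eps *= np.sqrt(tv[6] / eps.var())
    else:
        eps = np.zeros((K, T))

    log_panel = (
        alpha
        + psi[None, :]
        + (omega[u_idx] + delta[s_idx] + phi[p_idx] + gamma[c_idx] + xi)[:, None]
        + eps
    )
    years = tuple(range(first_year, first_year + T))
    panel = SpaceTimePanel(hierarchy.county_ids, years, np.exp(log_panel))
    truth = SimulationTruth(
        alpha=float(alpha),
        psi_true=psi,
        omega_true=omega,
        delta_true=delta,
        phi_true=phi,
        gamma_true=gamma,
        xi_true=xi,
        target_shares=shares,
        total_variance=float(total_variance),
        seed=int(seed),
    )
    return panel, truth
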