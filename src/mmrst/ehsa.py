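"""Emerging hotspot analysis and the category / threshold bookkeeping.

Pipeline: complete unit × time cube → space-time Getis-Ord Gi* z-scores
(cube-wide mean and SD so that z-series are comparable over time) →
Mann-Kendall trend on each unit's z-series → one of 17 patterns (eight
hot, eight cold, or no pattern) per unit, driven by bin significance,
significance prevalence, and trend direction.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpaceTimePanel
from .weights import SpaceTimeNeighborhood, SpatialWeights, space_time_neighbors

__all__ = [
    "SpaceTimeCube",
    "GiStarField",
    "EhsaResult",
    "getis_ord_gistar_st",
    "mann_kendall",
    "classify_ehsa",
    "emerging_hotspot_analysis",
    "summarize_categories",
    "sdg_classification",
    "percentage",
    "EHSA_CATEGORIES",
]

_HOT_KINDS = (
    "new",
    "consecutive",
    "intensifying",
    "persistent",
    "diminishing",
    "sporadic",
    "oscillating",
    "historical",
)
EHSA_CATEGORIES = tuple(
    f"{kind} {side} spot" for side in ("hot", "cold") for kind in _HOT_KINDS
) + ("no pattern detected",)


@dataclass
class SpaceTimeCube:
    """Complete unit × time value grid."""

    unit_ids: tuple[str, ...]
    times: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.times)):
            raise ValueError("cube shape mismatch")
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_panel(cls, panel: SpaceTimePanel) -> "SpaceTimeCube":
        return cls(panel.unit_ids, panel.years, panel.values)


@dataclass
class GiStarField:
    """Per-bin Gi* z-scores plus the cube-wide moments used."""

    z: np.ndarray = field(repr=False)
    mean: float
    sd: float
    sig_level: float
    degenerate: bool = False

    @property
    def z_crit(self) -> float:
        return float(stats.norm.ppf(1.0 - self.sig_level / 2.0))

    @property
    def hot(self) -> np.ndarray:
        return self.z >= self.z_crit

    @property
    def cold(self) -> np.ndarray:
        return self.z <= -self.z_crit


@dataclass
class EhsaResult:
    table: pd.DataFrame = field(repr=False)  # per unit
    summary: pd.DataFrame = field(repr=False)  # category counts / percentages
    gistar: GiStarField = field(repr=False, default=None)
    settings: dict = field(default_factory=dict)


def getis_ord_gistar_st(
    cube: SpaceTimeCube, nbhd: SpaceTimeNeighborhood, sig_level: float = 0.05
) -> GiStarField:
    """Space-time Gi* over self-inclusive spatio-temporal neighborhoods.

    For bin b with neighbor set N(b),

        z_b = (Σ_{b'∈N(b)} x_{b'} − X̄ |N(b)|)
              / (S sqrt((n |N(b)| − |N(b)|²) / (n − 1)))

    with n the total bin count and X̄, S the cube-wide mean and
    (population) standard deviation.  A constant cube is degenerate: all
    z are zero and flagged.
    """
    X = cube.values
    K, T = X.shape
    if nbhd.weights.n != K or nbhd.n_times != T:
        raise ValueError("neighborhood not built on the cube's units/times")
    n = K * T
    xbar = X.mean()
    sd = float(np.sqrt((X**2).mean() - xbar**2))
    if sd == 0.0:
        return GiStarField(np.zeros_like(X), xbar, 0.0, sig_level, degenerate=True)

    # spatial self-inclusive sums, then clipped temporal window sums
    a_plus_i = nbhd.weights.to_sparse() + _sparse_eye(K)
    sx = np.asarray(a_plus_i @ X)
    lag = nbhd.lag
    pad = np.zeros((K, 1))
    csum = np.concatenate([pad, np.cumsum(sx, axis=1)], axis=1)
    lo = np.maximum(np.arange(T) - lag, 0)
    hi = np.minimum(np.arange(T) + lag, T - 1)
    window_sum = csum[:, hi + 1] - csum[:, lo]

    counts = nbhd.counts().astype(float)
    num = window_sum - xbar * counts
    den = sd * np.sqrt((n * counts - counts**2) / (n - 1))
    z = num / den
    return GiStarField(z, float(xbar), sd, sig_level)


def _sparse_eye(k):
    import scipy.sparse as sp

    return sp.identity(k, format="csr")


def mann_kendall(series) -> tuple[int, float, float, float]:
    """Mann-Kendall trend test: returns (S, var_s, z, p).

    S sums the signs of all forward pairwise differences; the variance
    carries the tie correction; z applies the ±1 continuity correction
    (0 when S = 0); p is the two-sided normal tail.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("Mann-Kendall requires at least 2 observations")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    if var_s <= 0:
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return s, float(var_s), float(z), min(p, 1.0)


def classify_ehsa(
    z_series,
    sig_level: float = 0.05,
    prevalence: float = 0.90,
    trend_level: float = 0.05,
) -> str:
    """Classify one unit's Gi* z-series into one of the 17 patterns.

    Bin significance uses the two-sided normal critical value at
    ``sig_level``; 'consecutive' additionally requires a final run of at
    least two significant bins (distinguishing it from 'new').
    """
    z = np.asarray(z_series, dtype=float)
    if z.size < 2:
        raise ValueError("z-series must have length >= 2")
    crit = float(stats.norm.ppf(1.0 - sig_level / 2.0))
    _, _, mk_z, mk_p = mann_kendall(z)

    hot = z >= crit
    cold = z <= -crit
    cat_hot = _classify_side(hot, cold, mk_z, mk_p, prevalence, trend_level, "hot")
    cat_cold = _classify_side(cold, hot, -mk_z, mk_p, prevalence, trend_level, "cold")
    if cat_hot is not None and cat_cold is not None:
        # both sides fire (e.g. a long cold history ending on a hot bin):
        # the side of the final significant bin wins; with neither final
        # bin significant, the more prevalent side wins (tie: no pattern).
        if hot[-1]:
            return cat_hot
        if cold[-1]:
            return cat_cold
        if hot.mean() > cold.mean():
            return cat_hot
        if cold.mean() > hot.mean():
            return cat_cold
        return "no pattern detected"
    if cat_hot is not None:
        return cat_hot
    if cat_cold is not None:
        return cat_cold
    return "no pattern detected"


def _classify_side(sig, anti, mk_z, mk_p, prevalence, trend_level, side):
    """Hot-side rule set (mirrored for cold via negated inputs)."""
    share = sig.mean()
    final = bool(sig[-1])
    trend_up = mk_p <= trend_level and mk_z > 0
    trend_down = mk_p <= trend_level and mk_z < 0

    if share >= prevalence:
        if final:
            if trend_up:
                return f"intensifying {side} spot"
            if trend_down:
                return f"diminishing {side} spot"
            return f"persistent {side} spot"
        return f"historical {side} spot"
    if not final:
        return None
    if sig.sum() == 1:
        return f"new {side} spot"
    run = _final_run_length(sig)
    if run >= 2 and sig[:-run].sum() == 0:
        return f"consecutive {side} spot"
    if anti.any():
        return f"oscillating {side} spot"
    return f"sporadic {side} spot"


def _final_run_length(flags: np.ndarray) -> int:
    run = 0
    for v in flags[::-1]:
        if not v:
            break
        run += 1
    return run


def emerging_hotspot_analysis(
    panel: SpaceTimePanel,
    weights: SpatialWeights,
    lag: int = 1,
    sig_level: float = 0.05,
    prevalence: float = 0.90,
    trend_level: float = 0.05,
) -> EhsaResult:
    """Cube → space-time Gi* → per-unit pattern → category summary."""
    cube = SpaceTimeCube.from_panel(panel)
    nbhd = space_time_neighbors(weights, cube.values.shape[1], lag)
    gi = getis_ord_gistar_st(cube, nbhd, sig_level=sig_level)

    rows = []
    for i, unit in enumerate(cube.unit_ids):
        z = gi.z[i]
        _, _, mk_z, mk_p = mann_kendall(z)
        cat = (
            "no pattern detected"
            if gi.degenerate
            else classify_ehsa(z, sig_level, prevalence, trend_level)
        )
        rows.append(
            {
                "unit_id": unit,
                "category": cat,
                "percent_hot": 100.0 * float((z >= gi.z_crit).mean()),
                "percent_cold": 100.0 * float((z <= -gi.z_crit).mean()),
                "mk_z": mk_z,
                "mk_p": mk_p,
            }
        )
    table = pd.DataFrame(rows)
    counts = table["category"].value_counts().to_dict()
    summary = summarize_categories(counts, len(cube.unit_ids))
    settings = dict(
        lag=lag, sig_level=sig_level, prevalence=prevalence, trend_level=trend_level
    )
    return EhsaResult(table, summary, gi, settings)


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """100·count/total rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = decimal.Decimal(1).scaleb(-decimals)
    frac = decimal.Decimal(100 * int(count)) / decimal.Decimal(int(total))
    return float(frac.quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_categories(counts: dict[str, int], total: int) -> pd.DataFrame:
    """Category count / percentage table (half-up, 2 decimals)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    if sum(counts.values()) > total:
        raise ValueError("counts exceed total")
    rows = [
        {
            "category": cat,
            "count": int(cnt),
            "percentage": percentage(int(cnt), total),
        }
        for cat, cnt in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percentage"])


def sdg_classification(
    panel: SpaceTimePanel, threshold: float = 70.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold achievement bookkeeping: value strictly below threshold.

    Returns ``(flags, yearly)``: per unit-year achievement flags in long
    form, and per-year achieving counts with percentages.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    achieved = panel.values < threshold
    flags = panel.to_long_frame()
    flags["achieved"] = achieved.ravel()
    yearly = pd.DataFrame(
        {
            "year": panel.years,
            "achieved_count": achieved.sum(axis=0).astype(int),
            "total": panel.n_units,
        }
    )
    yearly["percentage"] = [
        percentage(c, panel.n_units) for c in yearly["achieved_count"]
    ]
    return flags, yearly
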