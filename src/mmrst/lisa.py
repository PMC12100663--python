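"""Anselin Local Moran's I with conditional-permutation inference.

Statistic (row-standardized weights, m2 with the /n denominator):

    I_i = (x_i − x̄) / m2 · Σ_j w_ij (x_j − x̄),   m2 = Σ_k (x_k − x̄)² / n

Inference is by conditional permutation: the value at unit i stays put
while neighbor values are resampled from the remaining n−1 observations.
The tail is taken on the sign of the observed statistic with the usual
+1 correction and folded (doubled) by default so that rejections are
calibrated under the null.  Units significant at ``alpha`` are
classified by the quadrant of (own deviation, spatial-lag deviation)
into high-high / low-low clusters and high-low / low-high outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpaceTimePanel
from .weights import SpatialWeights, row_standardize

__all__ = ["LisaResult", "local_morans_i", "lisa_by_year", "CATEGORIES"]

CATEGORIES = (
    "high-high",
    "low-low",
    "high-low",
    "low-high",
    "not-significant",
)


@dataclass
class LisaResult:
    """Per-unit local Moran statistics, inference, and categories."""

    table: pd.DataFrame = field(repr=False)
    settings: dict = field(default_factory=dict)
    constant_input: bool = False

    @property
    def categories(self) -> pd.Series:
        return self.table.set_index("unit_id")["category"]


def _multiple_test_adjust(p: np.ndarray, method: str | None, alpha: float) -> np.ndarray:
    """Per-unit significance mask under no / Bonferroni / BH-FDR correction."""
    ok = np.isfinite(p)
    sig = np.zeros(p.size, dtype=bool)
    if method is None:
        sig[ok] = p[ok] <= alpha
    elif method == "bonferroni":
        m = int(ok.sum())
        sig[ok] = p[ok] <= alpha / max(m, 1)
    elif method == "fdr":
        idx = np.flatnonzero(ok)
        ps = p[idx]
        order = np.argsort(ps)
        m = idx.size
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = ps[order] <= thresh
        k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
        sig[idx[order[:k]]] = True
    else:
        raise ValueError(f"unknown correction {method!r}")
    return sig


def local_morans_i(
    values,
    weights: SpatialWeights,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    correction: str | None = None,
    two_sided: bool = True,
) -> LisaResult:
    """Local Moran's I for one cross-section.

    ``weights`` may be binary (it is row-standardized internally) or
    already standardized.  ``permutations=0`` skips inference and returns
    analytical columns only (everything not-significant).

    The default p-value folds the direction-conditional permutation tail
    (doubled, capped at 1), which is calibrated under an exchangeable
    null; ``two_sided=False`` reports the raw one-sided tail on the
    observed sign instead (anti-conservative: ~2α rejections under the
    null).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("local Moran's I requires n >= 3")
    if n != weights.n:
        raise ValueError("values and weights are misaligned")
    if weights.weights is None:
        weights = row_standardize(weights)
    deg = weights.degrees
    if not (deg > 0).any():
        raise ValueError("no unit has neighbors")

    xbar = x.mean()
    z = x - xbar
    m2 = float(z @ z) / n
    settings = dict(permutations=permutations, alpha=alpha, seed=seed,
                    correction=correction, two_sided=two_sided)

    if m2 == 0.0:
        table = pd.DataFrame(
            {
                "unit_id": weights.ids,
                "I": np.nan,
                "expectation": np.nan,
                "lag": 0.0,
                "p_sim": np.nan,
                "z_sim": np.nan,
                "category": "not-significant",
            }
        )
        return LisaResult(table, settings, constant_input=True)

    lag = np.array(
        [
            float(weights.weights[i] @ z[weights.neighbors[i]])
            if deg[i]
            else np.nan
            for i in range(n)
        ]
    )
    local_i = z / m2 * lag
    # analytical expectation under total randomization, row-standardized
    expectation = np.where(deg > 0, -1.0 / (n - 1), np.nan)

    p_sim = np.full(n, np.nan)
    z_sim = np.full(n, np.nan)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        max_k = int(deg.max())
        # one pool of index draws shared across units (standard LISA trick):
        # rows are permutations of 0..n-2, columns truncated to max degree
        draws = np.argsort(rng.random((permutations, n - 1)), axis=1)[:, :max_k]
        for i in range(n):
            k = int(deg[i])
            if k == 0:
                continue
            others = np.delete(z, i)
            perm_lag = others[draws[:, :k]] @ weights.weights[i]
            perm_i = z[i] / m2 * perm_lag
            if local_i[i] >= 0:
                extreme = int(np.sum(perm_i >= local_i[i]))
            else:
                extreme = int(np.sum(perm_i <= local_i[i]))
            p_dir = (extreme + 1) / (permutations + 1)
            p_sim[i] = min(2.0 * p_dir, 1.0) if two_sided else p_dir
            sd = perm_i.std()
            z_sim[i] = (local_i[i] - perm_i.mean()) / sd if sd > 0 else np.nan

    significant = _multiple_test_adjust(p_sim, correction, alpha)
    category = np.full(n, "not-significant", dtype=object)
    for i in np.flatnonzero(significant):
        if z[i] >= 0:
            category[i] = "high-high" if lag[i] >= 0 else "high-low"
        else:
            category[i] = "low-low" if lag[i] < 0 else "low-high"

    table = pd.DataFrame(
        {
            "unit_id": weights.ids,
            "I": np.where(deg > 0, local_i, np.nan),
            "expectation": expectation,
            "lag": lag,
            "p_sim": p_sim,
            "z_sim": z_sim,
            "category": category,
        }
    )
    return LisaResult(table, settings)


def lisa_by_year(
    panel: SpaceTimePanel,
    weights: SpatialWeights,
    years=None,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    correction: str | None = None,
    two_sided: bool = True,
) -> dict[int, LisaResult]:
    """Run :func:`local_morans_i` on selected panel years.

    Each year gets an independent, deterministic substream of ``seed``.
    """
    if years is None:
        years = panel.years
    out: dict[int, LisaResult] = {}
    for year in years:
        x = panel.year_values(year)  # raises KeyError for absent years
        sub_seed = None if seed is None else np.random.SeedSequence(
            entropy=seed, spawn_key=(int(year),)
        )
        out[int(year)] = local_morans_i(
            x,
            weights,
            permutations=permutations,
            alpha=alpha,
            seed=sub_seed,
            correction=correction,
            two_sided=two_sided,
        )
    return out
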