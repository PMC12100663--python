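"""Bayesian multiscale spatiotemporally varying intercepts model.

Log-scale additive decomposition of a complete unit × year rate panel:

    log y_it = alpha + psi_t + omega_u(i) + delta_s(i) + phi_p(i)
               + gamma_c(i) + xi_i + eps_it

with a first-order random-walk prior on the national trend ``psi`` (a
second-order walk is available by flag), iid normal priors on the
rural/urban, region, province, and city intercepts, an intrinsic CAR
prior on the county surface ``xi`` (precision proportional to the
adjacency-graph Laplacian), and iid Gaussian residuals.  All precisions
carry Gamma(a, b) hyperpriors.  Inference is a blocked Gibbs sampler:
the structured blocks are sampled exactly from their Gaussian full
conditionals via a one-off eigendecomposition of each structure matrix,
and every random-effect block is recentred after its update (sum-to-zero
per connected component for ``xi``); a global intercept ``alpha``
carries the level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import AdminHierarchy, SpaceTimePanel
from .weights import SpatialWeights

__all__ = [
    "ModelSpec",
    "ModelStructures",
    "PosteriorDraws",
    "prepare_log_panel",
    "model_structures",
    "fit_bmstvi",
    "temporal_trend",
    "spatial_risk_maps",
    "split_rhat",
    "save_draws",
    "load_draws",
]

EFFECTS = ("psi", "omega", "delta", "phi", "gamma", "xi")
LEVEL_OF_EFFECT = {
    "omega": "rural-urban",
    "delta": "region",
    "phi": "province",
    "gamma": "city",
    "xi": "county",
}


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and prior settings.

    ``a``/``b`` are the Gamma hyperprior shape/rate shared by every
    precision (weakly informative default); ``disable`` pins listed
    effect blocks at zero (used for degenerate-model checks);
    ``fixed_precisions`` holds any precision at a constant instead of
    sampling it.
    """

    iterations: int = 5000
    burnin: int = 2000
    thin: int = 3
    chains: int = 2
    seed: int = 0
    a: float = 1.0
    b: float = 5e-4
    rw_order: int = 1
    zero_rule: str = "half_min"
    disable: frozenset = frozenset()
    fixed_precisions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.iterations > self.burnin >= 0:
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("hyperprior shape/rate must be positive")
        if self.rw_order not in (1, 2):
            raise ValueError("rw_order must be 1 or 2")
        bad = set(self.disable) - set(EFFECTS)
        if bad:
            raise ValueError(f"unknown effects in disable: {sorted(bad)}")


@dataclass
class ModelStructures:
    """Structure matrices of the two improper-prior blocks (and caches)."""

    rt: np.ndarray  # temporal random-walk structure, T x T
    laplacian: sp.csr_matrix  # county-graph Laplacian, K x K
    rw_order: int = 1
    _gv: dict = field(default_factory=dict, repr=False)

    @property
    def rank_rt(self) -> int:
        return self.rt.shape[0] - self.rw_order

    def gv(self, which: str) -> float:
        """Geometric mean of the diagonal of the generalized inverse."""
        if which not in self._gv:
            mat = self.rt if which == "psi" else self.laplacian.toarray()
            diag = np.diag(np.linalg.pinv(mat, hermitian=True))
            diag = diag[diag > 1e-12]
            if diag.size == 0:
                raise ValueError(f"structure for {which!r} is singular beyond "
                                 "its known null space")
            self._gv[which] = float(np.exp(np.mean(np.log(diag))))
        return self._gv[which]


def rw_structure(T: int, order: int = 1) -> np.ndarray:
    """Random-walk structure matrix DᵀD of the order-``order`` differences."""
    d = np.diff(np.eye(T), n=order, axis=0)
    return d.T @ d


def model_structures(
    weights: SpatialWeights, n_years: int, rw_order: int = 1
) -> ModelStructures:
    return ModelStructures(
        rt=rw_structure(n_years, rw_order),
        laplacian=weights.laplacian().tocsr(),
        rw_order=rw_order,
    )


def prepare_log_panel(panel: SpaceTimePanel, rule: str = "half_min",
                      offset: float = 1.0) -> np.ndarray:
    """Log-transform a nonnegative panel with a zero-handling rule.

    ``half_min`` replaces zeros by half the smallest positive value in
    the panel; ``offset`` adds a fixed offset to every cell; ``drop``
    marks zero cells NaN (callers must handle the gaps).
    """
    v = np.asarray(panel.values, dtype=float)
    if (v < 0).any():
        raise ValueError("panel values must be nonnegative")
    zeros = v == 0
    if zeros.all():
        raise ValueError("all-zero panel cannot be log-transformed")
    if rule == "half_min":
        if zeros.any():
            v = np.where(zeros, v[v > 0].min() / 2.0, v)
        return np.log(v)
    if rule == "offset":
        return np.log(v + offset)
    if rule == "drop":
        out = np.full(v.shape, np.nan)
        out[~zeros] = np.log(v[~zeros])
        return out
    raise ValueError(f"unknown zero rule {rule!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of every model quantity.

    Arrays are (draws, dim); chains are concatenated and ``n_chains`` /
    ``draws_per_chain`` record the layout for diagnostics.
    """

    alpha: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    xi: np.ndarray
    tau: dict[str, np.ndarray]  # keys: psi, omega, delta, phi, gamma, xi
    sigma2: np.ndarray
    years: tuple[int, ...]
    level_labels: dict[str, tuple[str, ...]]  # per level name
    level_index: dict[str, np.ndarray]  # county -> group index arrays
    n_chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    @property
    def draws_per_chain(self) -> int:
        return self.n_draws // self.n_chains

    def effect(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def by_chain(self, arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr).reshape(self.n_chains, self.draws_per_chain, -1)


def _group_setup(hierarchy: AdminHierarchy):
    idx, labels = {}, {}
    for eff, level in LEVEL_OF_EFFECT.items():
        if level == "county":
            idx[eff] = np.arange(hierarchy.n_counties)
            labels[level] = hierarchy.county_ids
        else:
            gi, labs = hierarchy.group_indices(level)
            idx[eff] = gi
            labels[level] = labs
    return idx, labels


def fit_bmstvi(
    log_panel: np.ndarray,
    hierarchy: AdminHierarchy,
    weights: SpatialWeights,
    spec: ModelSpec,
    years: tuple[int, ...] | None = None,
) -> PosteriorDraws:
    """Blocked Gibbs sampler for the multiscale model.

    ``log_panel`` is the K × T matrix of log rates (counties in
    ``hierarchy.county_ids`` order).  Returns concatenated post-burn-in,
    thinned draws from ``spec.chains`` chains.
    """
    Y = np.asarray(log_panel, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != hierarchy.n_counties:
        raise ValueError("log_panel must be (n_counties, n_years)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("log panel contains non-finite values; resolve zeros "
                         "before fitting")
    if tuple(weights.ids) != tuple(hierarchy.county_ids):
        raise ValueError("weights must be defined on the hierarchy's counties")

    K, T = Y.shape
    N = K * T
    structures = model_structures(weights, T, spec.rw_order)
    idx, labels = _group_setup(hierarchy)
    comp_labels = weights.connected_components()
    n_comp = int(comp_labels.max()) + 1

    # one-off eigendecompositions for exact Gaussian block sampling
    lam_t, vec_t = np.linalg.eigh(structures.rt)
    lam_s, vec_s = np.linalg.eigh(structures.laplacian.toarray())

    sizes = {
        "psi": T,
        "omega": 2,
        "delta": len(labels["region"]),
        "phi": len(labels["province"]),
        "gamma": len(labels["city"]),
        "xi": K,
    }
    iid_effects = ("omega", "delta", "phi", "gamma")
    group_counts = {
        eff: np.bincount(idx[eff], minlength=sizes[eff]) for eff in iid_effects
    }
    rank = {"psi": structures.rank_rt, "xi": K - n_comp}
    comp_members = [np.flatnonzero(comp_labels == c) for c in range(n_comp)]
    # child-group -> parent-group maps for the nested rebalance moves
    parent_of: dict[tuple[str, str], np.ndarray] = {}
    for parent, child in (("delta", "phi"), ("phi", "gamma")):
        arr = np.zeros(sizes[child], dtype=np.intp)
        arr[idx[child]] = idx[parent]
        parent_of[(parent, child)] = arr

    kept = (spec.iterations - spec.burnin + spec.thin - 1) // spec.thin
    total_kept = kept * spec.chains
    out = {
        "alpha": np.empty(total_kept),
        "sigma2": np.empty(total_kept),
        **{eff: np.empty((total_kept, sizes[eff])) for eff in EFFECTS},
    }
    out_tau = {eff: np.empty(total_kept) for eff in EFFECTS}

    row_sum_Y = Y.sum(axis=1)
    col_sum_Y = Y.sum(axis=0)
    active = [e for e in EFFECTS if e not in spec.disable]

    for chain in range(spec.chains):
        rng = np.random.default_rng([int(spec.seed), chain])
        eff = {e: np.zeros(sizes[e]) for e in EFFECTS}
        tau = {e: float(spec.fixed_precisions.get(e, 1.0)) for e in EFFECTS}
        sigma2 = float(np.var(Y)) or 1.0
        alpha = float(Y.mean())
        keep_at = chain * kept
        stored = 0

        for it in range(spec.iterations):
            spatial = (
                eff["omega"][idx["omega"]]
                + eff["delta"][idx["delta"]]
                + eff["phi"][idx["phi"]]
                + eff["gamma"][idx["gamma"]]
                + eff["xi"]
            )
            # -- alpha (flat prior)
            resid_mean = (
                Y.mean() - eff["psi"].mean() - (spatial * T).sum() / N
            )
            alpha = resid_mean + rng.standard_normal() * np.sqrt(sigma2 / N)

            # -- psi block
            if "psi" in active:
                b = (col_sum_Y - K * alpha - spatial.sum()) / sigma2
                d = tau["psi"] * lam_t + K / sigma2
                mu = vec_t @ ((vec_t.T @ b) / d)
                draw = mu + vec_t @ (rng.standard_normal(T) / np.sqrt(d))
                eff["psi"] = draw - draw.mean()

            # -- iid levels
            row_base = row_sum_Y - T * alpha - eff["psi"].sum()
            for name in iid_effects:
                if name not in active:
                    continue
                others = sum(
                    eff[o][idx[o]] for o in iid_effects if o != name
                ) + eff["xi"]
                partial = row_base - T * others
                gsum = np.bincount(idx[name], weights=partial,
                                   minlength=sizes[name])
                prec = tau[name] + group_counts[name] * T / sigma2
                mu = (gsum / sigma2) / prec
                draw = mu + rng.standard_normal(sizes[name]) / np.sqrt(prec)
                eff[name] = draw - draw.mean()

            # -- xi block (iCAR)
            if "xi" in active:
                others = sum(eff[o][idx[o]] for o in iid_effects)
                partial = row_base - T * others
                b = partial / sigma2
                d = tau["xi"] * lam_s + T / sigma2
                mu = vec_s @ ((vec_s.T @ b) / d)
                draw = mu + vec_s @ (rng.standard_normal(K) / np.sqrt(d))
                for members in comp_members:
                    draw[members] -= draw[members].mean()
                eff["xi"] = draw

            # -- rebalance nested iid level pairs (likelihood-invariant
            # Gibbs move on the parent/child split; cures the slow mixing
            # of precisions whose levels are confounded by nesting)
            for parent, child in (("delta", "phi"), ("phi", "gamma")):
                if parent not in active or child not in active:
                    continue
                par_of = parent_of[(parent, child)]
                kids_per = np.bincount(par_of, minlength=sizes[parent])
                child_sum = np.bincount(par_of, weights=eff[child],
                                        minlength=sizes[parent])
                prec = tau[parent] + kids_per * tau[child]
                mu = (tau[child] * child_sum - tau[parent] * eff[parent]) / prec
                m = mu + rng.standard_normal(sizes[parent]) / np.sqrt(prec)
                eff[parent] = eff[parent] + m
                eff[child] = eff[child] - m[par_of]
                eff[parent] -= eff[parent].mean()
                eff[child] -= eff[child].mean()

            # -- precisions
            for name in active:
                if name in spec.fixed_precisions:
                    continue
                if name == "psi":
                    quad = float(eff["psi"] @ structures.rt @ eff["psi"])
                    shape = spec.a + rank["psi"] / 2.0
                elif name == "xi":
                    quad = float(eff["xi"] @ (structures.laplacian @ eff["xi"]))
                    shape = spec.a + rank["xi"] / 2.0
                else:
                    quad = float(eff[name] @ eff[name])
                    shape = spec.a + sizes[name] / 2.0
                tau[name] = rng.gamma(shape, 1.0 / (spec.b + quad / 2.0))

            # -- residual variance
            spatial = (
                eff["omega"][idx["omega"]]
                + eff["delta"][idx["delta"]]
                + eff["phi"][idx["phi"]]
                + eff["gamma"][idx["gamma"]]
                + eff["xi"]
            )
            resid = Y - alpha - eff["psi"][None, :] - spatial[:, None]
            tau_eps = rng.gamma(
                spec.a + N / 2.0, 1.0 / (spec.b + float((resid**2).sum()) / 2.0)
            )
            sigma2 = 1.0 / tau_eps
            if sigma2 < 1e-12:
                raise RuntimeError("residual variance collapsed below 1e-12")

            if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0:
                j = keep_at + stored
                out["alpha"][j] = alpha
                out["sigma2"][j] = sigma2
                for name in EFFECTS:
                    out[name][j] = eff[name]
                    out_tau[name][j] = tau[name] if name in active else np.nan
                stored += 1
        assert stored == kept

    return PosteriorDraws(
        alpha=out["alpha"],
        psi=out["psi"],
        omega=out["omega"],
        delta=out["delta"],
        phi=out["phi"],
        gamma=out["gamma"],
        xi=out["xi"],
        tau=out_tau,
        sigma2=out["sigma2"],
        years=tuple(years) if years is not None else tuple(range(T)),
        level_labels=labels,
        level_index={e: idx[e] for e in EFFECTS if e != "psi"},
        n_chains=spec.chains,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def _summarize(draws_2d: np.ndarray, exponentiate: bool = False) -> pd.DataFrame:
    a = np.exp(draws_2d) if exponentiate else draws_2d
    qs = np.percentile(a, [2.5, 25.0, 75.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": a.mean(axis=0),
            "lo95": qs[0],
            "lo50": qs[1],
            "hi50": qs[2],
            "hi95": qs[3],
        }
    )


def temporal_trend(draws: PosteriorDraws, exponentiate: bool = False) -> pd.DataFrame:
    """Posterior mean and 50%/95% equal-tailed bands of the yearly trend."""
    df = _summarize(draws.psi, exponentiate)
    df.insert(0, "year", list(draws.years))
    return df


def spatial_risk_maps(draws: PosteriorDraws, level: str) -> pd.DataFrame:
    """Relative risk exp(effect) per unit of an administrative level."""
    eff_name = {v: k for k, v in LEVEL_OF_EFFECT.items()}.get(level)
    if eff_name is None:
        raise ValueError(
            f"level must be one of {sorted(LEVEL_OF_EFFECT.values())}"
        )
    df = _summarize(draws.effect(eff_name), exponentiate=True)
    df.insert(0, "unit", list(draws.level_labels[level]))
    return df


def equal_interval_bands(values, k: int = 5) -> np.ndarray:
    """1-based equal-interval band per value (display helper)."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.size, dtype=int)
    band = np.floor((v - lo) / (hi - lo) * k).astype(int) + 1
    return np.clip(band, 1, k)


def split_rhat(x: np.ndarray, n_chains: int, rank_normalize: bool = True) -> float:
    """Split-chain potential-scale-reduction diagnostic for a scalar chain.

    Rank normalization (the modern default) makes the diagnostic robust
    for heavy-tailed quantities such as precisions.
    """
    x = np.asarray(x, dtype=float)
    if rank_normalize:
        from scipy import stats as _stats

        ranks = _stats.rankdata(x)
        x = _stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
    x = x.reshape(n_chains, -1)
    half = x.shape[1] // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# persistence


def save_draws(draws: PosteriorDraws, csv_path, manifest_path) -> None:
    """Persist draws as a wide CSV plus a JSON manifest of the layout."""
    cols: dict[str, np.ndarray] = {"alpha": draws.alpha, "sigma2": draws.sigma2}
    for name in EFFECTS:
        arr = draws.effect(name)
        for j in range(arr.shape[1]):
            cols[f"{name}[{j}]"] = arr[:, j]
        cols[f"tau_{name}"] = draws.tau[name]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    manifest = {
        "n_chains": draws.n_chains,
        "years": list(draws.years),
        "level_labels": {k: list(v) for k, v in draws.level_labels.items()},
        "level_index": {k: v.tolist() for k, v in draws.level_index.items()},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh)


def load_draws(csv_path, manifest_path) -> PosteriorDraws:
    df = pd.read_csv(csv_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    def block(name):
        sub = [c for c in df.columns if c.startswith(f"{name}[")]
        sub.sort(key=lambda c: int(c[len(name) + 1 : -1]))
        return df[sub].to_numpy()

    return PosteriorDraws(
        alpha=df["alpha"].to_numpy(),
        psi=block("psi"),
        omega=block("omega"),
        delta=block("delta"),
        phi=block("phi"),
        gamma=block("gamma"),
        xi=block("xi"),
        tau={e: df[f"tau_{e}"].to_numpy() for e in EFFECTS},
        sigma2=df["sigma2"].to_numpy(),
        years=tuple(manifest["years"]),
        level_labels={
            k: tuple(v) for k, v in manifest["level_labels"].items()
        },
        level_index={
            k: np.asarray(v, dtype=np.intp)
            for k, v in manifest["level_index"].items()
        },
        n_chains=int(manifest["n_chains"]),
    )
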