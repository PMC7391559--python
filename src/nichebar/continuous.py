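"""Continuous-trait evolutionary models and GLS ancestral estimation.

This is the traditional baseline the binned approach is compared against:
summarize each species' niche as a single number (e.g. median suitable
mean annual temperature), fit Gaussian trait-evolution models on the tree
— Brownian motion (BM), Ornstein–Uhlenbeck (OU), early burst (EB) and BM
with a linear drift ("trend") — pick the best by AIC, and estimate
ancestral values as the best linear unbiased predictor (conditional
expectation) under the fitted covariance.

Model-implied tip covariances (unit rate, shared time t_ij, depths d_i):

* BM     : t_ij
* OU     : e^{-alpha (d_i + d_j - 2 t_ij)} (1 - e^{-2 alpha t_ij}) / (2 alpha)
           (conditional on the root sitting at the optimum; this form
           converges to BM as alpha -> 0, keeping BM nested in OU)
* EB     : (e^{r t_ij} - 1) / r, r <= 0 (rate decays as sigma0^2 e^{r t})
* trend  : BM covariance with mean mu + beta * depth

sigma^2 and the mean parameters are profiled analytically; only alpha (OU)
and r (EB) need numerical optimization, done multi-start on a log/linear
scale.  On an ultrametric tree the trend drift beta is confounded with the
root mean; the fit then uses a pseudoinverse and warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny

MODELS = ("bm", "ou", "eb", "trend")

_PARAM_COUNT = {"bm": 2, "ou": 3, "eb": 3, "trend": 3}


@dataclass
class FittedModel:
    model: str
    params: dict[str, float]     # sigma2 and model-specific parameters
    log_likelihood: float
    k: int
    tip_labels: tuple[str, ...]
    tip_values: tuple[float, ...]

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood


def _tree_geometry(tree: Phylogeny):
    """Depths of all nodes and ancestor paths (as index lists, root last)."""
    depths = np.array(tree.depths())
    paths = []
    for v in range(tree.n_nodes):
        path = [v]
        while tree.parent[path[-1]] != -1:
            path.append(tree.parent[path[-1]])
        paths.append(path)
    return depths, paths


def _mrca_depth(paths, depths, a: int, b: int) -> float:
    sb = set(paths[b])
    for u in paths[a]:
        if u in sb:
            return depths[u]
    raise AssertionError("no common ancestor")


def _shared_time_matrix(tree: Phylogeny, nodes_a: Sequence[int], nodes_b: Sequence[int]):
    depths, paths = _tree_geometry(tree)
    T = np.empty((len(nodes_a), len(nodes_b)))
    for i, a in enumerate(nodes_a):
        for j, b in enumerate(nodes_b):
            T[i, j] = depths[a] if a == b else _mrca_depth(paths, depths, a, b)
    return T


def _unit_cov(model: str, T: np.ndarray, da: np.ndarray, db: np.ndarray, shape: dict):
    """Covariance at sigma2 = 1 between node sets with depths da, db."""
    if model in ("bm", "trend"):
        return T.copy()
    if model == "ou":
        alpha = shape["alpha"]
        # below this the OU covariance is BM to machine noise; returning BM
        # exactly keeps BM nested at the bottom of the alpha search range
        if alpha * max(float(np.max(da, initial=0.0)), float(np.max(db, initial=0.0)), 1.0) < 1e-7:
            return T.copy()
        E = np.exp(-alpha * (da[:, None] + db[None, :] - 2 * T))
        return E * (1.0 - np.exp(-2 * alpha * T)) / (2 * alpha)
    if model == "eb":
        r = shape["r"]
        if abs(r) < 1e-12:
            return T.copy()
        return np.expm1(r * T) / r
    raise ValueError(f"unknown model {model!r}")


def _design(model: str, depths: np.ndarray, ultrametric: bool):
    if model == "trend":
        return np.column_stack([np.ones_like(depths), depths])
    return np.ones((len(depths), 1))


def _profile_loglik(C: np.ndarray, X: np.ndarray, x: np.ndarray):
    """ML profile of sigma2 and the mean coefficients for V = sigma2 * C."""
    n = len(x)
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance: {exc}") from exc
    Cinv_X = cho_solve(cf, X)
    Cinv_x = cho_solve(cf, x)
    XtCX = X.T @ Cinv_X
    try:
        beta = np.linalg.solve(XtCX, X.T @ Cinv_x)
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(XtCX) @ (X.T @ Cinv_x)
    resid = x - X @ beta
    sigma2 = float(resid @ cho_solve(cf, resid) / n)
    if sigma2 <= 0:
        sigma2 = 1e-300
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return loglik, sigma2, beta


def _align(tree: Phylogeny, trait: Mapping[str, float]):
    tips = tree.tip_indices
    labels = [tree.labels[v] for v in tips]
    missing = set(labels) - set(trait)
    if missing:
        raise ValueError(f"trait missing for tips: {sorted(missing)}")
    x = np.array([float(trait[l]) for l in labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return tips, labels, x


def fit_evo_model(tree: Phylogeny, trait: Mapping[str, float], model: str) -> FittedModel:
    """ML fit of one trait-evolution model to tip values on the tree."""
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    tips, labels, x = _align(tree, trait)
    if len(tips) < 2:
        raise ValueError("need at least 2 tips to fit a model")
    ultrametric = tree.is_ultrametric(tol=1e-6)
    if model in ("ou", "eb") and not ultrametric:
        warnings.warn(f"{model} fit on a non-ultrametric tree", stacklevel=2)
    if model == "trend" and ultrametric:
        warnings.warn(
            "trend drift is confounded with the root mean on an ultrametric tree",
            stacklevel=2,
        )

    depths = np.array(tree.depths())
    dt = depths[tips]
    T = _shared_time_matrix(tree, tips, tips)
    height = float(dt.max())
    X = _design(model, dt, ultrametric)

    def fit_at(shape: dict):
        C = _unit_cov(model, T, dt, dt, shape)
        return _profile_loglik(C, X, x)

    def best_scalar(obj, lo: float, hi: float, xatol: float) -> float:
        # OU/EB profile likelihoods can be flat or multimodal in the shape
        # parameter; search three overlapping sub-intervals and keep the best.
        span = hi - lo
        windows = [(lo, lo + 0.5 * span), (lo + 0.25 * span, lo + 0.75 * span), (lo + 0.5 * span, hi)]
        best_x, best_f = None, np.inf
        for a, b in windows:
            res = minimize_scalar(obj, bounds=(a, b), method="bounded", options={"xatol": xatol})
            if res.fun < best_f:
                best_x, best_f = float(res.x), float(res.fun)
        return best_x

    shape: dict[str, float] = {}
    if model == "ou":
        lo, hi = np.log(1e-8 / height), np.log(100.0 / height)
        y = best_scalar(lambda y: -fit_at({"alpha": float(np.exp(y))})[0], lo, hi, 1e-8)
        shape["alpha"] = float(np.exp(y))
    elif model == "eb":
        shape["r"] = best_scalar(
            lambda r: -fit_at({"r": float(r)})[0], -10.0 / height, 0.0, 1e-10
        )

    loglik, sigma2, beta = fit_at(shape)
    if not np.isfinite(loglik):
        raise ValueError(f"{model} fit did not converge (logLik={loglik})")
    params = {"sigma2": sigma2, **shape}
    if model == "trend":
        params["mu"] = float(beta[0])
        params["beta"] = float(beta[1])
    elif model == "ou":
        params["theta"] = float(beta[0])
    else:
        params["mu"] = float(beta[0])
    return FittedModel(
        model=model,
        params=params,
        log_likelihood=float(loglik),
        k=_PARAM_COUNT[model],
        tip_labels=tuple(labels),
        tip_values=tuple(x),
    )


def select_model(fits: Sequence[FittedModel]) -> FittedModel:
    """Minimum-AIC model; exact ties broken toward fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    ref = (fits[0].tip_labels, fits[0].tip_values)
    for f in fits[1:]:
        if (f.tip_labels, f.tip_values) != ref:
            raise ValueError("fits were made on different data")
    return min(fits, key=lambda f: (f.aic, f.k))


@dataclass
class NodeEstimate:
    node_id: str
    estimate: float
    se: float


def continuous_asr(
    tree: Phylogeny, trait: Mapping[str, float], fitted: FittedModel
) -> dict[str, NodeEstimate]:
    """GLS/BLUP ancestral estimates at every internal node.

    Each node's estimate is its conditional expectation given the tips
    under the fitted model (with the fitted mean plugged in); the SE is the
    square root of the conditional variance.
    """
    tips, labels, x = _align(tree, trait)
    if tuple(labels) != fitted.tip_labels or tuple(x) != fitted.tip_values:
        raise ValueError("fitted model was not fit on this tree/trait")
    model, p = fitted.model, fitted.params
    shape = {k: v for k, v in p.items() if k in ("alpha", "r")}
    sigma2 = p["sigma2"]

    depths = np.array(tree.depths())
    dt = depths[tips]
    internal = tree.internal_indices
    di = depths[internal]

    Ctt = sigma2 * _unit_cov(model, _shared_time_matrix(tree, tips, tips), dt, dt, shape)
    Cnt = sigma2 * _unit_cov(model, _shared_time_matrix(tree, internal, tips), di, dt, shape)
    Cnn_diag = sigma2 * np.array(
        [
            _unit_cov(model, np.array([[depths[v]]]), depths[[v]], depths[[v]], shape)[0, 0]
            for v in internal
        ]
    )

    if model == "trend":
        m_tips = p["mu"] + p["beta"] * dt
        m_nodes = p["mu"] + p["beta"] * di
    else:
        mu = p.get("mu", p.get("theta"))
        m_tips = np.full(len(tips), mu)
        m_nodes = np.full(len(internal), mu)

    cf = cho_factor(Ctt)
    w = cho_solve(cf, x - m_tips)
    est = m_nodes + Cnt @ w
    var = Cnn_diag - np.einsum("ij,ij->i", Cnt, cho_solve(cf, Cnt.T).T)
    var = np.maximum(var, 0.0)
    return {
        tree.labels[v]: NodeEstimate(tree.labels[v], float(est[i]), float(np.sqrt(var[i])))
        for i, v in enumerate(internal)
    }


def simulate_trait(
    tree: Phylogeny, model: str, params: Mapping[str, float], rng: np.random.Generator
) -> dict[str, float]:
    """Draw one tip-trait realization under a model (used for self-tests)."""
    tips = tree.tip_indices
    depths = np.array(tree.depths())
    dt = depths[tips]
    shape = {k: v for k, v in params.items() if k in ("alpha", "r")}
    C = params["sigma2"] * _unit_cov(
        model, _shared_time_matrix(tree, tips, tips), dt, dt, shape
    )
    if model == "trend":
        m = params["mu"] + params["beta"] * dt
    else:
        m = np.full(len(tips), params.get("mu", params.get("theta", 0.0)))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tips)))
    x = m + L @ rng.standard_normal(len(tips))
    return {tree.labels[v]: float(x[i]) for i, v in enumerate(tips)}
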