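"""ML fitting and AICc comparison of continuous-trait evolutionary models.

Six single-regime models of a continuous trait on a time-calibrated tree,
all expressed as transforms of the Brownian shared-ancestry matrix C (entries
in My; T = tree depth):

=======  ==========================================================
model    tip covariance (before the sigma2 multiplier)
=======  ==========================================================
BM       C
EB       (exp(a*C) - 1)/a, a < 0 (ACDC / early burst; -> C as a -> 0)
delta    C**delta, rescaled so the max diagonal equals T
SSP      (1/(2*alpha)) * exp(-2*alpha*(T - C)) * (1 - exp(-2*alpha*C))
         (single-stationary-peak Ornstein-Uhlenbeck on an ultrametric tree;
         -> C as alpha -> 0)
lambda   off-diagonal entries multiplied by lambda in [0, 1]
WN       identity (white noise: no phylogenetic structure)
=======  ==========================================================

Each model's tip distribution is MVN(z0 * 1, sigma2 * V_model + diag(se^2))
where se are within-tip standard errors; z0 is profiled by GLS, sigma2 and
the shape parameter are optimized numerically with seeded restarts. Models
are compared by small-sample AICc and Akaike weights; the favoured model is
the lowest-AICc one unless a model with fewer parameters sits within 2 AICc
units, in which case the simplest such model wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .signal import align_to_tips, gls_mean_loglik
from .tree import Phylogeny, TreeError

__all__ = [
    "MODELS",
    "ModelFit",
    "AncestralStates",
    "PglsResult",
    "ContinuousTraitModel",
    "ModelComparison",
    "model_covariance",
    "fit_trait_model",
    "fit_model_set",
    "bm_ancestral_states",
    "pgls_regression",
    "default_shape_bounds",
]

MODELS = ("BM", "EB", "delta", "SSP", "lambda", "WN")
SHAPE_NAME = {"EB": "a", "delta": "delta", "SSP": "alpha", "lambda": "lambda"}
LOG_SIGMA2_BOUNDS = (math.log(1e-12), math.log(1e4))
BOUND_TOL = 1e-6


def default_shape_bounds(model: str, depth: float) -> tuple[float, float] | None:
    """Default box constraints for each model's shape parameter.

    EB's upper bound of -1e-6 keeps the transform strictly "decelerating";
    estimates pinned there are flagged ``at_bound`` (their true value may be
    smaller in magnitude). Bounds scale with tree depth T where the
    parameter has units of 1/My.
    """
    if model in ("BM", "WN"):
        return None
    return {
        "EB": (-10.0 / depth, -1e-6),
        "delta": (1e-5, 3.0),
        "SSP": (1e-8, 50.0 / depth),
        "lambda": (0.0, 1.0),
    }[model]


def model_covariance(model: str, shape: float | None, C: np.ndarray,
                     depth: float, rescale_depth: bool = True) -> np.ndarray:
    """Transformed shared-ancestry matrix for one model.

    ``rescale_depth`` (delta only) rescales so the maximum diagonal entry
    equals the tree depth, keeping sigma2 comparable across delta values.
    """
    if model == "BM":
        return C.copy()
    if model == "WN":
        return np.eye(C.shape[0])
    if shape is None:
        raise ValueError(f"model {model} requires a shape parameter")
    if model == "EB":
        a = float(shape)
        if a == 0:
            return C.copy()
        return np.expm1(a * C) / a
    if model == "delta":
        d = float(shape)
        if d <= 0:
            raise ValueError("delta must be positive")
        V = C**d
        if rescale_depth:
            m = V.diagonal().max()
            if m > 0:
                V = V * (depth / m)
        return V
    if model == "SSP":
        al = float(shape)
        if al < 0:
            raise ValueError("alpha must be non-negative")
        if al == 0:
            return C.copy()
        return (1.0 / (2.0 * al)) * np.exp(-2.0 * al * (depth - C)) * (-np.expm1(-2.0 * al * C))
    if model == "lambda":
        lam = float(shape)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        V = C * lam
        np.fill_diagonal(V, C.diagonal())
        return V
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


@dataclass(frozen=True)
class ModelFit:
    """One model's ML solution and information-criterion bookkeeping."""

    model: str
    sigma2: float
    z0: float
    shape: float | None
    log_lik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan
    at_bound: bool = False
    converged: bool = True

    @property
    def shape_name(self) -> str | None:
        return SHAPE_NAME.get(self.model)

    def summary(self) -> str:
        rows = [
            f"Model: {self.model}   (n = {self.n} tips, k = {self.k} parameters)",
            f"  sigma2:   {self.sigma2:.6g}",
            f"  z0:       {self.z0:.6g}",
        ]
        if self.shape is not None:
            star = "*" if self.at_bound else ""
            rows.append(f"  {self.shape_name}:{' ' * max(1, 9 - len(self.shape_name))}{self.shape:.6g}{star}")
        rows += [
            f"  lnLik:    {self.log_lik:.4f}",
            f"  AICc:     {self.aicc:.4f}",
        ]
        if np.isfinite(self.delta_aicc):
            rows.append(f"  dAICc:    {self.delta_aicc:.4f}   weight: {self.akaike_weight:.4f}")
        if self.at_bound:
            rows.append("  * shape parameter estimated at an optimization bound")
        return "\n".join(rows)


def _aicc(log_lik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} <= k + 1 = {k + 1}")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class ContinuousTraitModel:
    """Single-trait evolutionary model on a phylogeny (statsmodels style).

    Parameters
    ----------
    tree : Phylogeny
    trait : mapping or array
        Complete tip values (ln mm in the body-size application).
    se : mapping or array, optional
        Within-tip standard errors; added to the tip variance as diag(se^2).
    model : str
        One of ``BM, EB, delta, SSP, lambda, WN``.
    shape_bounds : (low, high), optional
        Override the default box for the shape parameter.
    rescale_depth : bool
        Depth-preserving rescaling of the delta transform (default True).

    ``fit()`` returns a :class:`ModelFit`.
    """

    def __init__(self, tree: Phylogeny, trait, se=None, model: str = "BM",
                 shape_bounds=None, rescale_depth: bool = True):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        self.tree = tree
        self.model = model
        self.x = align_to_tips(tree, trait, "trait")
        n = self.x.size
        if n < 4:
            raise ValueError("need at least 4 tips to fit a trait model")
        if se is None:
            self.se = np.zeros(n)
        else:
            self.se = align_to_tips(tree, se, "se")
            if np.any(self.se < 0):
                raise ValueError("se must be non-negative")
        self.C = tree.covariance()
        self.depth = tree.depth
        if model == "SSP" and not tree.is_ultrametric():
            raise TreeError("SSP (stationary-peak OU) requires an ultrametric tree")
        self.rescale_depth = rescale_depth
        self.shape_bounds = (
            tuple(shape_bounds) if shape_bounds is not None
            else default_shape_bounds(model, self.depth)
        )

    # likelihood of (log sigma2, shape); z0 profiled by GLS
    def _loglik(self, log_s2: float, shape: float | None):
        Vm = model_covariance(self.model, shape, self.C, self.depth,
                              self.rescale_depth)
        V = math.exp(log_s2) * Vm + np.diag(self.se**2)
        try:
            ll, z0, _, _ = gls_mean_loglik(V, self.x)
        except np.linalg.LinAlgError:
            return -np.inf, np.nan
        return ll, z0

    def loglik(self, sigma2: float, shape: float | None = None) -> float:
        """Profile log-likelihood at given parameters (z0 profiled out)."""
        ll, _ = self._loglik(math.log(sigma2), shape)
        return ll

    def _shape_to_opt(self, s):
        lo, hi = self.shape_bounds
        if self.model in ("delta", "SSP"):   # positive, log-transformed
            return math.log(s)
        return float(s)

    def _shape_from_opt(self, t):
        if self.model in ("delta", "SSP"):
            return math.exp(t)
        return float(t)

    def fit(self, n_starts: int = 5, seed: int = 0) -> ModelFit:
        n = self.x.size
        k = 2 if self.model in ("BM", "WN") else 3
        if self.model in ("BM", "WN"):
            res = optimize.minimize_scalar(
                lambda ls: -self._loglik(ls, None)[0],
                bounds=LOG_SIGMA2_BOUNDS, method="bounded",
                options={"xatol": 1e-10},
            )
            log_s2, shape, converged = float(res.x), None, bool(res.success)
        else:
            lo, hi = self.shape_bounds
            tlo, thi = self._shape_to_opt(max(lo, 1e-300) if self.model in ("delta", "SSP") else lo), \
                self._shape_to_opt(hi)
            if self.model == "lambda":
                tlo, thi = lo, hi
            rng = np.random.default_rng(seed)
            # moment-based sigma2 start at the shape-box centre, then
            # seeded random restarts
            ls0 = math.log(max(np.var(self.x), 1e-8) / max(self.depth, 1e-8))
            starts = [(ls0, 0.5 * (tlo + thi))]
            for _ in range(max(0, n_starts - 1)):
                starts.append((
                    rng.uniform(math.log(1e-8), math.log(1e2)),
                    rng.uniform(tlo, thi),
                ))
            best, converged = None, False
            for s0 in starts:
                r = optimize.minimize(
                    lambda th: -self._loglik(th[0], self._shape_from_opt(th[1]))[0],
                    x0=np.asarray(s0),
                    method="L-BFGS-B",
                    bounds=[LOG_SIGMA2_BOUNDS, (tlo, thi)],
                    options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
                )
                if best is None or r.fun < best.fun:
                    best = r
                converged = converged or bool(r.success)
            if best is None or not np.isfinite(best.fun):
                raise RuntimeError(
                    f"{self.model}: optimizer failed to converge after {n_starts} restarts"
                )
            if not converged:
                warnings.warn(f"{self.model}: no optimizer restart reported convergence")
            log_s2 = float(best.x[0])
            shape = self._shape_from_opt(float(best.x[1]))
        ll, z0 = self._loglik(log_s2, shape)
        if not np.isfinite(ll):
            raise RuntimeError(f"{self.model}: non-finite likelihood at optimum")
        at_bound = False
        if shape is not None:
            lo, hi = self.shape_bounds
            span = max(abs(hi - lo), 1e-12)
            at_bound = min(abs(shape - lo), abs(shape - hi)) <= BOUND_TOL * span
        return ModelFit(
            model=self.model, sigma2=math.exp(log_s2), z0=float(z0),
            shape=shape, log_lik=float(ll), k=k, n=n,
            aicc=_aicc(float(ll), k, n), at_bound=at_bound, converged=converged,
        )


def fit_trait_model(tree, trait, se=None, model="BM", shape_bounds=None,
                    n_starts: int = 5, seed: int = 0,
                    rescale_depth: bool = True) -> ModelFit:
    """Functional wrapper around :class:`ContinuousTraitModel`."""
    return ContinuousTraitModel(
        tree, trait, se=se, model=model, shape_bounds=shape_bounds,
        rescale_depth=rescale_depth,
    ).fit(n_starts=n_starts, seed=seed)


class ModelComparison:
    """AICc-ranked set of :class:`ModelFit` results with Akaike weights."""

    def __init__(self, fits: list[ModelFit]):
        if len(fits) < 1:
            raise ValueError("need at least one fitted model")
        aiccs = np.array([f.aicc for f in fits])
        dd = aiccs - aiccs.min()
        w = np.exp(-dd / 2.0)
        w = w / w.sum()
        self.fits = [
            replace(f, delta_aicc=float(d), akaike_weight=float(wi))
            for f, d, wi in zip(fits, dd, w)
        ]
        self.fits.sort(key=lambda f: f.aicc)

    @property
    def favoured(self) -> ModelFit:
        """Lowest AICc, unless a simpler model is within 2 AICc units."""
        best = self.fits[0]
        within = [f for f in self.fits if f.delta_aicc <= 2.0]
        kmin = min(f.k for f in within)
        if kmin < best.k:
            return min((f for f in within if f.k == kmin), key=lambda f: f.aicc)
        return best

    def summary(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({
                "model": f.model,
                "sigma2": f.sigma2,
                "z0": f.z0,
                "shape": f.shape if f.shape is not None else np.nan,
                "shape_name": f.shape_name or "",
                "lnLik": f.log_lik,
                "k": f.k,
                "AICc": f.aicc,
                "delta_AICc": f.delta_aicc,
                "akaike_weight": f.akaike_weight,
                "at_bound": f.at_bound,
                "favoured": f.model == self.favoured.model,
            })
        return pd.DataFrame(rows)


def fit_model_set(tree, trait, se=None, models=MODELS, shape_bounds=None,
                  n_starts: int = 5, seed: int = 0,
                  rescale_depth: bool = True) -> ModelComparison:
    """Fit several models to the same data and rank them by AICc.

    ``shape_bounds`` may be a mapping model -> (low, high) overriding the
    defaults for specific models.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    fits = []
    for m in models:
        sb = None
        if shape_bounds is not None:
            sb = shape_bounds.get(m) if hasattr(shape_bounds, "get") else shape_bounds
        fits.append(fit_trait_model(
            tree, trait, se=se, model=m, shape_bounds=sb,
            n_starts=n_starts, seed=seed, rescale_depth=rescale_depth,
        ))
    return ModelComparison(fits)


# ----------------------------------------------------------------------
# ancestral states
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AncestralStates:
    """BM joint-ML states at internal nodes (node id -> state, ln mm)."""

    states: dict[int, float]
    root: int
    sigma2: float
    z0: float

    @property
    def root_state(self) -> float:
        return self.states[self.root]


def bm_ancestral_states(tree: Phylogeny, trait, se=None) -> AncestralStates:
    """Joint ML (= GLS) ancestral states under BM with tip error.

    The BM rate and root state are fitted by ML, then each internal node's
    state is the conditional expectation
    ``z0 + sigma2 * c_node' V^{-1} (x - z0)`` where ``c_node[i]`` is the
    shared root-ward path length between the node and tip i.
    """
    x = align_to_tips(tree, trait, "trait")
    sev = np.zeros(x.size) if se is None else align_to_tips(tree, se, "se")
    C = tree.covariance()
    if np.all(sev == 0):
        # closed-form ML: z0 by GLS, sigma2 = quad/n (sigma2 then cancels
        # from the conditional expectation, so any n >= 2 works)
        _, z0, quad, _ = gls_mean_loglik(C, x)
        sigma2 = quad / x.size if quad > 0 else 1.0
    else:
        fit = fit_trait_model(tree, trait, se=se, model="BM")
        sigma2, z0 = fit.sigma2, fit.z0
    V = sigma2 * C + np.diag(sev**2)
    resid = np.linalg.solve(V, x - z0)
    depth = tree.node_depths()
    tip_pos = {nd: k for k, nd in enumerate(tree.tip_ids)}
    n = x.size
    # tips below each node
    below = {nd: [] for nd in range(tree.n_nodes)}
    for nd in tree.postorder():
        if tree.is_tip(nd):
            below[nd] = [tip_pos[nd]]
        else:
            below[nd] = [i for c in tree.children(nd) for i in below[c]]
    states: dict[int, float] = {}
    for nd in range(tree.n_nodes):
        if tree.is_tip(nd):
            continue
        c = np.empty(n)
        inside = below[nd]
        c[:] = 0.0
        c[inside] = depth[nd]
        # tips outside the clade share the depth of the relevant ancestor
        anc = nd
        prev_inside = set(inside)
        while tree.parent(anc) >= 0:
            anc = tree.parent(anc)
            for i in below[anc]:
                if i not in prev_inside:
                    c[i] = depth[anc]
            prev_inside = set(below[anc])
        states[nd] = float(z0 + sigma2 * (c @ resid))
    return AncestralStates(states=states, root=tree.root,
                           sigma2=float(sigma2), z0=float(z0))


# ----------------------------------------------------------------------
# PGLS
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PglsResult:
    """Brownian-covariance GLS regression of one tip trait on another."""

    slope: float
    intercept: float
    se: float
    t: float
    p: float
    n: int
    df_resid: int

    def summary(self) -> str:
        return (
            "PGLS (Brownian covariance)\n"
            f"  n = {self.n}, residual df = {self.df_resid}\n"
            f"  slope:     {self.slope:.4f}  (SE {self.se:.4f})\n"
            f"  intercept: {self.intercept:.4f}\n"
            f"  t = {self.t:.4f}, two-sided p = {self.p:.4g}"
        )


def pgls_regression(tree: Phylogeny, y, x) -> PglsResult:
    """GLS regression of y on x with the Brownian covariance C.

    Fits intercept + slope; the slope's standard error, t (n - 2 df) and
    two-sided p come from the GLS normal equations (delegated to
    statsmodels).
    """
    yv = align_to_tips(tree, y, "y")
    xv = align_to_tips(tree, x, "x")
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor")
    if yv.size < 4:
        raise ValueError("need at least 4 tips")
    C = tree.covariance()
    X = sm.add_constant(xv)
    res = sm.GLS(yv, X, sigma=C).fit()
    return PglsResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        se=float(res.bse[1]), t=float(res.tvalues[1]),
        p=float(res.pvalues[1]), n=yv.size, df_resid=int(res.df_resid),
    )
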