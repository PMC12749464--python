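"""Outcome models: multinomial logit, proportional-odds ordered logit, NB2
negative binomial, and binary logistic regression, with analytic-weight
support for inverse-probability-weighted refits.

The models are written statsmodels-style: a model object is built from an
outcome vector and a design matrix, ``fit()`` maximizes the (weighted)
log-likelihood by Newton–Raphson with backtracking line search (quasi-Newton
fallback), and returns a results object carrying coefficients, standard
errors from the inverse observed information, log-likelihood, pseudo-R², and
a ``summary()`` table with two-sided Wald stars at 0.05/0.01/0.001.

Families:

* multinomial logit  — P(c|x) = exp(x'b_c) / sum_k exp(x'b_k), reference
  category with b = 0; used for trajectory-cluster membership.
* ordered logit      — P(Y <= m | x) = logistic(kappa_m - x'b) with strictly
  increasing cutpoints; used for 5-category self-rated health (effects
  reportable as odds ratios).
* negative binomial (NB2) — mean mu = exp(x'b), variance mu + alpha*mu^2,
  dispersion reported as lnalpha; used for the 0–8 CESD symptom count
  (effects reportable as incidence-rate ratios).
* logistic           — used for the sample-inclusion model behind IPW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln

GTOL = 1e-6
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

CLUSTER_ORDER = [
    "never_married",
    "married_30s_widowed",
    "married_divorced",
    "married_20s_continuous",
    "married_by20_continuous",
    "married_remarried",
]
REFERENCE_CLUSTER = "married_20s_continuous"
PGS_COLUMNS = ["pgs_ea", "pgs_wb", "pgs_dep", "pgs_bmi"]
PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
SES_NUMERIC = ["educ_years", "mother_educ", "father_educ"]
CHILDHOOD_SES_LEVELS = ["poor", "average", "well_off", "varied_missing"]
COHORT_LEVELS = ["pre1948", "c1948_1959", "post1960"]


def stars(p: float) -> str:
    for cut, s in STAR_LEVELS:
        if p < cut:
            return s
    return ""


# ---------------------------------------------------------------------------
# generic MLE machinery


class ConvergenceError(RuntimeError):
    pass


class _MLEModel:
    """Base class: subclasses provide nll/grad (and optionally hess)."""

    family = "mle"

    def __init__(self, endog, exog, weights=None, param_names=None):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        n = self.endog.shape[0]
        if self.exog.shape[0] != n:
            raise ValueError("endog/exog row mismatch")
        self.weights = (np.ones(n) if weights is None
                        else np.asarray(weights, dtype=float))
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        self.param_names = param_names
        self.nobs = n

    # subclasses: nll(params), grad(params), start_params(); hess optional
    def hess(self, params: np.ndarray) -> np.ndarray:
        return _fd_hessian(self.grad, params)

    def fit(self, maxiter: int = 200, gtol: float = GTOL) -> "MLEResults":
        x = np.asarray(self.start_params(), dtype=float)
        converged = False
        used_fallback = False
        for _ in range(maxiter):
            g = self.grad(x)
            if np.abs(g).max() < gtol:
                converged = True
                break
            H = self.hess(x)
            step = _newton_step(H, g)
            x_new, ok = _line_search(self.nll, x, step, g)
            if not ok:
                used_fallback = True
                break
            x = x_new
        if not converged and not used_fallback:
            used_fallback = True
        if used_fallback and not converged:
            for _ in range(3):  # quasi-Newton restarts with Newton polish
                res = optimize.minimize(self.nll, x, jac=self.grad,
                                        method="BFGS",
                                        options={"gtol": gtol / 10,
                                                 "maxiter": 2000})
                x = res.x
                for _ in range(20):
                    g = self.grad(x)
                    if np.abs(g).max() < gtol:
                        break
                    step = _newton_step(self.hess(x), g)
                    x_new, ok = _line_search(self.nll, x, step, g)
                    if not ok:
                        break
                    x = x_new
                if np.abs(self.grad(x)).max() < gtol:
                    break
            converged = np.abs(self.grad(x)).max() < gtol
        H = self.hess(x)
        cov = _safe_inv(H)
        return MLEResults(model=self, params=x, cov=cov, llf=-self.nll(x),
                          converged=bool(converged),
                          max_grad=float(np.abs(self.grad(x)).max()))

    def null_model(self) -> "_MLEModel":
        raise NotImplementedError


def _fd_hessian(grad, x: np.ndarray) -> np.ndarray:
    p = len(x)
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-6 * (1.0 + abs(x[j]))
        e = np.zeros(p)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


def _newton_step(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    ridge = 0.0
    eye = np.eye(len(g))
    for _ in range(8):
        try:
            step = np.linalg.solve(H + ridge * eye, -g)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8)
            continue
        if np.dot(step, -g) > 0:  # descent direction for the nll
            return step
        ridge = max(ridge * 10, 1e-8)
    return -g  # steepest descent as last resort


def _line_search(nll, x, step, g, max_halvings: int = 30):
    f0 = nll(x)
    slope = np.dot(g, step)
    t = 1.0
    for _ in range(max_halvings):
        x_new = x + t * step
        f_new = nll(x_new)
        if np.isfinite(f_new) and f_new <= f0 + 1e-4 * t * slope:
            return x_new, True
        t *= 0.5
    return x, False


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


@dataclass
class MLEResults:
    """Estimates, uncertainties and diagnostics for one fitted model."""

    model: _MLEModel
    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    max_grad: float = float("nan")
    _llnull: float | None = field(default=None, repr=False)

    @property
    def separation_suspected(self) -> bool:
        """Divergent coefficients (quasi-separation): the likelihood is
        maximized on the boundary and the reported estimate is truncated."""
        return bool((not self.converged) and np.abs(self.params).max() > 20)

    @property
    def param_names(self) -> list[str]:
        names = self.model.param_names
        return names if names is not None else [f"x{i}" for i in range(len(self.params))]

    @property
    def bse(self) -> np.ndarray:
        var = np.diag(self.cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        return 2 * norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    @property
    def llnull(self) -> float:
        if self._llnull is None:
            self._llnull = self.model.null_model().fit().llf
        return self._llnull

    @property
    def pseudo_r2(self) -> float:
        """McFadden's pseudo-R^2."""
        return 1.0 - self.llf / self.llnull

    @property
    def pseudo_r2_coxsnell(self) -> float:
        return 1.0 - np.exp(2 * (self.llnull - self.llf) / self.model.nobs)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def tidy(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "term": self.param_names,
            "estimate": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "p": self.pvalues,
        })
        df["stars"] = [stars(p) for p in df["p"]]
        return df

    def summary(self) -> str:
        head = (f"{type(self.model).__name__}  n={self.nobs}  "
                f"llf={self.llf:.3f}  llnull={self.llnull:.3f}  "
                f"pseudo-R2(McFadden)={self.pseudo_r2:.4f}  "
                f"converged={self.converged}")
        body = self.tidy().to_string(
            index=False,
            formatters={"estimate": "{:9.4f}".format, "se": "{:8.4f}".format,
                        "z": "{:7.3f}".format, "p": "{:7.4f}".format},
        )
        return head + "\n" + body


# ---------------------------------------------------------------------------
# binary logistic


class Logit(_MLEModel):
    family = "logistic"

    def __init__(self, endog, exog, weights=None, param_names=None):
        super().__init__(endog, exog, weights, param_names)
        y = self.endog.astype(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("logistic outcome must be 0/1")
        self.y = y

    def nll(self, params):
        eta = self.exog @ params
        return float(-np.sum(self.weights * (self.y * eta - np.logaddexp(0, eta))))

    def grad(self, params):
        mu = expit(self.exog @ params)
        return -self.exog.T @ (self.weights * (self.y - mu))

    def hess(self, params):
        mu = expit(self.exog @ params)
        w = self.weights * mu * (1 - mu)
        return (self.exog * w[:, None]).T @ self.exog

    def start_params(self):
        return np.zeros(self.exog.shape[1])

    def predict(self, params, exog=None):
        X = self.exog if exog is None else np.asarray(exog, dtype=float)
        return expit(X @ params)

    def null_model(self):
        return Logit(self.y, np.ones((self.nobs, 1)), self.weights, ["const"])


# ---------------------------------------------------------------------------
# multinomial logit


class MultinomialLogit(_MLEModel):
    """Reference-category multinomial logit; endog holds codes 0..K-1 with 0
    the reference.  Parameters are stored flat, category-major."""

    family = "multinomial_logit"

    def __init__(self, endog, exog, weights=None, param_names=None,
                 category_names=None):
        super().__init__(endog, exog, weights, param_names)
        y = self.endog.astype(int)
        self.k_cats = int(y.max()) + 1
        if self.k_cats < 2:
            raise ValueError("need at least two outcome categories")
        self.y = y
        self.category_names = (category_names if category_names is not None
                               else [str(c) for c in range(self.k_cats)])
        p = self.exog.shape[1]
        if self.param_names is None:
            xn = [f"x{i}" for i in range(p)]
            self.param_names = [f"{self.category_names[k]}:{v}"
                                for k in range(1, self.k_cats) for v in xn]
        self._onehot = np.zeros((self.nobs, self.k_cats - 1))
        for k in range(1, self.k_cats):
            self._onehot[:, k - 1] = y == k

    def _probs(self, params):
        B = params.reshape(self.k_cats - 1, self.exog.shape[1])
        eta = self.exog @ B.T                      # n x (K-1)
        full = np.column_stack([np.zeros(self.nobs), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def nll(self, params):
        P = self._probs(params)
        ll = np.log(np.clip(P[np.arange(self.nobs), self.y], 1e-300, None))
        return float(-np.sum(self.weights * ll))

    def grad(self, params):
        P = self._probs(params)[:, 1:]             # n x (K-1)
        resid = self.weights[:, None] * (self._onehot - P)
        return -(resid.T @ self.exog).ravel()

    def hess(self, params):
        P = self._probs(params)[:, 1:]
        p = self.exog.shape[1]
        K1 = self.k_cats - 1
        H = np.empty((K1 * p, K1 * p))
        for k in range(K1):
            for l in range(k, K1):
                wkl = self.weights * (P[:, k] * ((k == l) - P[:, l]))
                block = (self.exog * wkl[:, None]).T @ self.exog
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = block
                H[l * p:(l + 1) * p, k * p:(k + 1) * p] = block.T
        return H

    def start_params(self):
        return np.zeros((self.k_cats - 1) * self.exog.shape[1])

    def predict(self, params, exog=None):
        if exog is None:
            return self._probs(params)
        X = np.asarray(exog, dtype=float)
        B = params.reshape(self.k_cats - 1, X.shape[1])
        eta = X @ B.T
        full = np.column_stack([np.zeros(X.shape[0]), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def null_model(self):
        return MultinomialLogit(self.y, np.ones((self.nobs, 1)), self.weights,
                                category_names=self.category_names)

    def params_frame(self, results: MLEResults) -> pd.DataFrame:
        p = self.exog.shape[1]
        B = results.params.reshape(self.k_cats - 1, p)
        cols = [n.split(":", 1)[1] for n in self.param_names[:p]]
        return pd.DataFrame(B, index=self.category_names[1:], columns=cols)


# ---------------------------------------------------------------------------
# ordered logit (proportional odds)


class OrderedLogit(_MLEModel):
    """P(Y <= m | x) = logistic(kappa_m - x'b); endog codes 0..M-1.

    The design must not contain an intercept (absorbed by the cutpoints).
    Parameters are [b, kappa_1..kappa_{M-1}].
    """

    family = "ordered_logit"

    def __init__(self, endog, exog, weights=None, param_names=None,
                 collapse_empty: bool = True):
        endog = np.asarray(endog).astype(int)
        levels = np.unique(endog)
        if collapse_empty:
            remap = {v: i for i, v in enumerate(levels)}
            if len(levels) != endog.max() + 1 or levels[0] != 0:
                warnings.warn("collapsing empty/offset outcome categories")
            endog = np.array([remap[v] for v in endog])
        super().__init__(endog, exog, weights, param_names)
        if _has_constant(self.exog):
            raise ValueError("ordered logit design must exclude the constant")
        self.y = self.endog.astype(int)
        self.n_levels = int(self.y.max()) + 1
        if self.n_levels < 2:
            raise ValueError("need at least two outcome categories")
        self.k_exog = self.exog.shape[1]
        if self.param_names is None:
            self.param_names = [f"x{i}" for i in range(self.k_exog)]
        self.param_names = list(self.param_names) + [
            f"cut{j}" for j in range(1, self.n_levels)
        ]

    def _split(self, params):
        return params[: self.k_exog], params[self.k_exog:]

    def _cdf_terms(self, params):
        beta, kappa = self._split(params)
        eta = self.exog @ beta if self.k_exog else np.zeros(self.nobs)
        kpad = np.concatenate([[-np.inf], kappa, [np.inf]])
        u = kpad[self.y + 1] - eta
        l = kpad[self.y] - eta
        Fu, Fl = expit(u), expit(l)
        fu = np.where(np.isfinite(u), Fu * (1 - Fu), 0.0)
        fl = np.where(np.isfinite(l), Fl * (1 - Fl), 0.0)
        P = np.clip(Fu - Fl, 1e-300, None)
        return P, fu, fl

    def nll(self, params):
        P, _, _ = self._cdf_terms(params)
        return float(-np.sum(self.weights * np.log(P)))

    def grad(self, params):
        P, fu, fl = self._cdf_terms(params)
        w = self.weights
        g_beta = -(self.exog.T @ (w * (fl - fu) / P)) if self.k_exog else np.empty(0)
        g_kappa = np.zeros(self.n_levels - 1)
        ratio_u = w * fu / P
        ratio_l = w * fl / P
        for j in range(self.n_levels - 1):
            g_kappa[j] = -(ratio_u[self.y == j].sum() - ratio_l[self.y == j + 1].sum())
        return np.concatenate([g_beta, g_kappa])

    def start_params(self):
        shares = np.array([self.weights[self.y == m].sum()
                           for m in range(self.n_levels)])
        cum = np.cumsum(shares / shares.sum())[:-1]
        cum = np.clip(cum, 1e-6, 1 - 1e-6)
        kappa = np.log(cum / (1 - cum))
        return np.concatenate([np.zeros(self.k_exog), kappa])

    def predict(self, params, exog=None):
        """Category probabilities, n x M."""
        beta, kappa = self._split(params)
        X = self.exog if exog is None else np.asarray(exog, dtype=float)
        eta = X @ beta if self.k_exog else np.zeros(X.shape[0])
        kpad = np.concatenate([[-np.inf], kappa, [np.inf]])
        cdf = expit(kpad[None, :] - eta[:, None])
        return np.diff(cdf, axis=1)

    def null_model(self):
        return OrderedLogit(self.y, np.empty((self.nobs, 0)), self.weights, [])


def _has_constant(X: np.ndarray) -> bool:
    return X.shape[1] > 0 and (np.ptp(X, axis=0) == 0).any() and X.size > 0


# ---------------------------------------------------------------------------
# negative binomial (NB2)


class NegativeBinomial(_MLEModel):
    """NB2 count regression; parameters are [b, lnalpha]."""

    family = "negative_binomial"
    _ETA_CAP = 300.0  # keeps exp() finite; never binding at realistic scales

    def __init__(self, endog, exog, weights=None, param_names=None):
        super().__init__(endog, exog, weights, param_names)
        y = self.endog.astype(float)
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("count outcome must be nonnegative integers")
        self.y = y
        if self.param_names is None:
            self.param_names = [f"x{i}" for i in range(self.exog.shape[1])]
        self.param_names = list(self.param_names) + ["lnalpha"]

    def _mu_alpha(self, params):
        beta, lnalpha = params[:-1], params[-1]
        eta = np.clip(self.exog @ beta, -self._ETA_CAP, self._ETA_CAP)
        return np.exp(eta), np.exp(np.clip(lnalpha, -40.0, 40.0))

    def nll(self, params):
        mu, a = self._mu_alpha(params)
        y = self.y
        inv_a = 1.0 / a
        ll = (gammaln(y + inv_a) - gammaln(inv_a) - gammaln(y + 1)
              - (y + inv_a) * np.log1p(a * mu) + y * np.log(a) + y * np.log(mu))
        return float(-np.sum(self.weights * ll))

    def grad(self, params):
        mu, a = self._mu_alpha(params)
        y, w = self.y, self.weights
        g_beta = -self.exog.T @ (w * (y - mu) / (1 + a * mu))
        inv_a = 1.0 / a
        dll_da = (inv_a ** 2 * (digamma(inv_a) - digamma(y + inv_a)
                                + np.log1p(a * mu))
                  + (y - mu) / (a * (1 + a * mu)))
        g_lnalpha = -np.sum(w * dll_da) * a
        return np.concatenate([g_beta, [g_lnalpha]])

    def start_params(self):
        ybar = max(np.average(self.y, weights=self.weights), 0.01)
        beta = np.zeros(self.exog.shape[1])
        if _has_constant(self.exog):
            const = int(np.nonzero(np.ptp(self.exog, axis=0) == 0)[0][0])
            beta[const] = np.log(ybar)
        s2 = np.average((self.y - ybar) ** 2, weights=self.weights)
        alpha0 = max((s2 - ybar) / ybar ** 2, 0.05)
        return np.concatenate([beta, [np.log(alpha0)]])

    def fit(self, maxiter: int = 200, gtol: float = GTOL) -> MLEResults:
        res = super().fit(maxiter=maxiter, gtol=gtol)
        if res.params[-1] < -12:
            warnings.warn("dispersion at the Poisson boundary (alpha -> 0)")
        return res

    def predict(self, params, exog=None):
        X = self.exog if exog is None else np.asarray(exog, dtype=float)
        return np.exp(np.clip(X @ params[:-1], -self._ETA_CAP, self._ETA_CAP))

    def null_model(self):
        return NegativeBinomial(self.y, np.ones((self.nobs, 1)),
                                self.weights, ["const"])


# ---------------------------------------------------------------------------
# specification plumbing


@dataclass
class ModelSpec:
    """One model specification in the staged series."""

    outcome: str                       # 'cluster' | 'srh' | 'cesd' | custom
    family: str                        # multinomial_logit | ordered_logit |
                                       # negative_binomial | logistic
    blocks: tuple[str, ...] = ("clusters",)
    reference_cluster: str = REFERENCE_CLUSTER
    stratum: str = "all"               # all | male | female
    weights_col: str | None = None
    include_pcs_with_pgs: bool = True


#: the five-stage predictor series reported for each health outcome
STAGE_BLOCKS = {
    1: ("clusters",),
    2: ("pgs",),
    3: ("clusters", "pgs"),
    4: ("clusters", "ses", "controls"),
    5: ("clusters", "pgs", "ses", "controls"),
}


def _dummies(series: pd.Series, levels: list[str], ref: str, prefix: str) -> pd.DataFrame:
    out = {}
    for lev in levels:
        if lev == ref:
            continue
        out[f"{prefix}[{lev}]"] = (series == lev).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Expand predictor blocks into a numeric design frame (no constant)."""
    cols: list[pd.DataFrame] = []
    if "clusters" in spec.blocks:
        cols.append(_dummies(data["cluster"], CLUSTER_ORDER,
                             spec.reference_cluster, "cluster"))
    if "pgs" in spec.blocks:
        cols.append(data[PGS_COLUMNS].astype(float))
        if spec.include_pcs_with_pgs:
            pcs = [c for c in PC_COLUMNS if c in data.columns]
            if pcs:
                cols.append(data[pcs].astype(float))
    if "ses" in spec.blocks:
        cols.append(data[SES_NUMERIC].astype(float))
        cols.append(_dummies(data["childhood_ses"], CHILDHOOD_SES_LEVELS,
                             "poor", "ses"))
    if "controls" in spec.blocks:
        ctl = {}
        if spec.stratum == "all":
            ctl["female"] = data["female"].astype(float)
        ctl["birth_year"] = data["birth_year"].astype(float)
        ctl_df = pd.DataFrame(ctl, index=data.index)
        cols.append(ctl_df)
        cols.append(_dummies(data["cohort"], COHORT_LEVELS, "pre1948", "cohort"))
        agediff = f"agediff_{spec.outcome}"
        if agediff in data.columns:
            cols.append(data[[agediff]].astype(float))
    if not cols:
        raise ValueError("specification has no predictor blocks")
    return pd.concat(cols, axis=1)


def _subset(data: pd.DataFrame, spec: ModelSpec, extra_cols=()) -> pd.DataFrame:
    df = data
    if spec.stratum == "male":
        df = df[df["female"] == 0]
    elif spec.stratum == "female":
        df = df[df["female"] == 1]
    elif spec.stratum != "all":
        raise ValueError(f"unknown stratum {spec.stratum!r}")
    needed = _columns_needed(spec) + list(extra_cols)
    needed = [c for c in dict.fromkeys(needed) if c in df.columns]
    return df.dropna(subset=needed)  # listwise deletion


def _columns_needed(spec: ModelSpec) -> list[str]:
    cols = [spec.outcome] if spec.outcome in ("srh", "cesd") else []
    if spec.outcome == "cluster" or "clusters" in spec.blocks:
        cols.append("cluster")
    if "pgs" in spec.blocks:
        cols += PGS_COLUMNS
    if "ses" in spec.blocks:
        cols += SES_NUMERIC + ["childhood_ses"]
    if "controls" in spec.blocks:
        cols += ["birth_year", "cohort", f"agediff_{spec.outcome}"]
    if spec.weights_col:
        cols.append(spec.weights_col)
    return cols


def _drop_constant_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance design columns (absent categories in a stratum)."""
    const = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if const:
        warnings.warn(f"dropping constant design columns: {const}")
        X = X.drop(columns=const)
    return X


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> MLEResults:
    """Fit one specification; dispatches on the model family."""
    df = _subset(data, spec)
    X = _drop_constant_columns(build_design(df, spec))
    w = df[spec.weights_col].to_numpy(float) if spec.weights_col else None
    names = list(X.columns)
    Xv = X.to_numpy(float)
    if spec.family == "multinomial_logit":
        order = [spec.reference_cluster] + [c for c in CLUSTER_ORDER
                                            if c != spec.reference_cluster]
        present = [c for c in order if (df["cluster"] == c).any()]
        codes = df["cluster"].map({c: i for i, c in enumerate(present)}).to_numpy()
        Xc = np.column_stack([np.ones(len(df)), Xv])
        model = MultinomialLogit(codes, Xc, weights=w,
                                 category_names=present,
                                 param_names=[f"{c}:{v}" for c in present[1:]
                                              for v in ["const"] + names])
    elif spec.family == "ordered_logit":
        model = OrderedLogit(df[spec.outcome].to_numpy(int) - 1, Xv,
                             weights=w, param_names=names)
    elif spec.family == "negative_binomial":
        Xc = np.column_stack([np.ones(len(df)), Xv])
        model = NegativeBinomial(df[spec.outcome].to_numpy(int), Xc,
                                 weights=w, param_names=["const"] + names)
    elif spec.family == "logistic":
        Xc = np.column_stack([np.ones(len(df)), Xv])
        model = Logit(df[spec.outcome].to_numpy(int), Xc, weights=w,
                      param_names=["const"] + names)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    res = model.fit()
    if not res.converged:
        warnings.warn(f"fit did not reach gradient tolerance for {spec}")
    return res


fit_multinomial = fit_model
fit_ordered_logit = fit_model
fit_negbin = fit_model


def run_model_series(
    data: pd.DataFrame,
    outcomes: dict[str, str] | None = None,
    strata: tuple[str, ...] = ("all", "male", "female"),
    stages: tuple[int, ...] = (1, 2, 3, 4, 5),
    weights_col: str | None = None,
) -> dict[tuple[str, str, int], MLEResults]:
    """The staged specification series: every outcome x stratum x stage."""
    if outcomes is None:
        outcomes = {"srh": "ordered_logit", "cesd": "negative_binomial"}
    fits: dict[tuple[str, str, int], MLEResults] = {}
    for outcome, family in outcomes.items():
        for stratum in strata:
            for stage in stages:
                spec = ModelSpec(outcome=outcome, family=family,
                                 blocks=STAGE_BLOCKS[stage], stratum=stratum,
                                 weights_col=weights_col)
                fits[(outcome, stratum, stage)] = fit_model(spec, data)
    return fits


def series_table(fits: dict[tuple[str, str, int], MLEResults]) -> pd.DataFrame:
    """Tidy long table over the whole series (term, estimate, se, stars...)."""
    rows = []
    for (outcome, stratum, stage), res in fits.items():
        t = res.tidy()
        t.insert(0, "outcome", outcome)
        t.insert(1, "stratum", stratum)
        t.insert(2, "stage", stage)
        t["n"] = res.nobs
        t["llf"] = res.llf
        t["pseudo_r2"] = res.pseudo_r2
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# interactions


def fit_interactions(
    spec: ModelSpec, data: pd.DataFrame, terms: tuple[str, ...],
    pgs: str | None = None,
) -> MLEResults:
    """Augment the specification with gender x cluster (and optionally
    gender x cluster x PGS) interactions, all lower-order terms included."""
    allowed = {"gender_x_cluster", "gender_x_cluster_x_pgs"}
    bad = set(terms) - allowed
    if bad:
        raise ValueError(f"unsupported interaction terms {sorted(bad)}")
    if "gender_x_cluster_x_pgs" in terms and pgs is None:
        raise ValueError("three-way interaction needs a pgs name")
    if spec.stratum != "all":
        raise ValueError("interaction models use the pooled sample")
    df = _subset(data, spec, extra_cols=("female",))
    X = build_design(df, spec)
    fem = df["female"].astype(float)
    cdums = _dummies(df["cluster"], CLUSTER_ORDER, spec.reference_cluster, "cluster")
    extra = {}
    for c in cdums.columns:
        extra[f"female:{c}"] = fem * cdums[c]
    if "gender_x_cluster_x_pgs" in terms:
        z = df[pgs].astype(float)
        extra[f"female:{pgs}"] = fem * z
        for c in cdums.columns:
            extra[f"{c}:{pgs}"] = cdums[c] * z
            extra[f"female:{c}:{pgs}"] = fem * cdums[c] * z
    X = _drop_constant_columns(pd.concat([X, pd.DataFrame(extra, index=df.index)],
                                         axis=1))
    _check_rank(X)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    w = df[spec.weights_col].to_numpy(float) if spec.weights_col else None
    if spec.family == "ordered_logit":
        model = OrderedLogit(df[spec.outcome].to_numpy(int) - 1, Xv, w, names)
    elif spec.family == "negative_binomial":
        Xc = np.column_stack([np.ones(len(df)), Xv])
        model = NegativeBinomial(df[spec.outcome].to_numpy(int), Xc, w,
                                 ["const"] + names)
    else:
        raise ValueError("interaction models support ordered_logit / negative_binomial")
    return model.fit()


def _check_rank(X: pd.DataFrame) -> None:
    # rank via QR with column pivoting on the raw design plus intercept
    from scipy.linalg import qr

    M = np.column_stack([np.ones(X.shape[0]), X.to_numpy(float)])
    _, R, piv = qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(M.shape) * np.finfo(float).eps * 10
    bad = piv[diag < tol]
    if bad.size:
        cols = ["const"] + list(X.columns)
        raise ValueError("rank-deficient design; aliased columns: "
                         + ", ".join(cols[i] for i in bad))


def predicted_probability_grid(
    results: MLEResults, data: pd.DataFrame, spec: ModelSpec, pgs: str,
    clusters: tuple[str, ...], grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted ordered-logit category probabilities over a PGS grid,
    by gender and trajectory cluster, other covariates held at sample means.

    Returns one row per (gender, cluster, grid point) with columns
    ``p1..pM`` (category probabilities; each row sums to 1).
    """
    model = results.model
    if not isinstance(model, OrderedLogit):
        raise ValueError("probability surfaces are for ordered-logit fits")
    if grid is None:
        grid = np.linspace(-3, 3, 13)
    df = _subset(data, spec, extra_cols=("female",))
    X = build_design(df, spec)
    cdum_names = [c for c in X.columns if c.startswith("cluster[")]
    base = X.mean(axis=0)
    rows, meta = [], []
    beta_names = results.param_names[: model.k_exog]
    for female in (0.0, 1.0):
        for cl in clusters:
            key = f"cluster[{cl}]"
            if key not in cdum_names and cl != spec.reference_cluster:
                raise ValueError(f"cluster {cl!r} not in the design")
            for g in grid:
                x = base.copy()
                if "female" in x.index:
                    x["female"] = female
                for cd in cdum_names:
                    x[cd] = 1.0 if cd == key else 0.0
                x[pgs] = g
                # interaction columns are products of their ':'-joined parts
                for name in beta_names:
                    if ":" in name:
                        parts = name.split(":")
                        x[name] = float(np.prod([
                            female if p == "female"
                            else g if p == pgs
                            else float(x.get(p, 0.0))
                            for p in parts
                        ]))
                rows.append([float(x.get(n, 0.0)) for n in beta_names])
                meta.append((female, cl, g))
    P = model.predict(results.params, np.asarray(rows))
    out = pd.DataFrame(meta, columns=["female", "cluster", pgs])
    for m in range(P.shape[1]):
        out[f"p{m + 1}"] = P[:, m]
    return out


# ---------------------------------------------------------------------------
# inverse probability weights


def compute_ipw(
    roster: pd.DataFrame,
    included: str | pd.Series = "included",
    covariates: tuple[str, ...] = ("birth_year", "cohort", "female"),
    p_floor: float = 0.01,
) -> pd.DataFrame:
    """Inclusion-model IPW: logistic regression of analytic-sample inclusion
    on birth year, birth cohort, and gender; weights 1/p-hat for included
    persons, normalized to mean one."""
    flag = (roster[included] if isinstance(included, str) else included)
    y = np.asarray(flag).astype(int)
    parts = []
    names = []
    for c in covariates:
        col = roster[c]
        if col.dtype.kind in "OUS" or str(col.dtype) == "category":
            levels = list(pd.unique(col))
            d = _dummies(col, levels, levels[0], c)
            parts.append(d.to_numpy(float))
            names += list(d.columns)
        else:
            parts.append(col.to_numpy(float)[:, None])
            names.append(c)
    X = np.column_stack([np.ones(len(roster))] + parts)
    res = Logit(y, X, param_names=["const"] + names).fit()
    p_hat = res.model.predict(res.params)
    low = p_hat < p_floor
    if low.any():
        warnings.warn(f"winsorizing {int(low.sum())} inclusion probabilities "
                      f"below {p_floor}")
        p_hat = np.clip(p_hat, p_floor, None)
    out = roster[["person_id"]].copy() if "person_id" in roster.columns \
        else pd.DataFrame(index=roster.index)
    out["p_hat"] = p_hat
    out["included"] = y
    out = out[out["included"] == 1].copy()
    w = 1.0 / out["p_hat"].to_numpy()
    out["weight"] = w / w.mean()
    return out.drop(columns=["included"])


# ---------------------------------------------------------------------------
# descriptives


def descriptives(data: pd.DataFrame, by: str = "female") -> pd.DataFrame:
    """Mean/SD (shares for indicator-expanded categoricals), pooled and by
    stratum."""
    df = data.copy()
    cat_cols = [c for c in df.columns
                if df[c].dtype.kind in "OUS" and c not in ("person_id",)]
    for c in cat_cols:
        for lev in pd.unique(df[c].dropna()):
            df[f"{c}[{lev}]"] = (df[c] == lev).astype(float)
    num = df.select_dtypes(include=[np.number])
    out = pd.DataFrame({"mean_all": num.mean(), "sd_all": num.std(ddof=1)})
    if by in df.columns:
        for val, tag in ((0, "male"), (1, "female")):
            sub = num[df[by] == val]
            out[f"mean_{tag}"] = sub.mean()
            out[f"sd_{tag}"] = sub.std(ddof=1)
    return out
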