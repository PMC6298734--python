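"""Delta (hurdle) species distribution models as penalized-spline GAMs.

The two model stages are

* a binomial GAM with a logit link for presence/absence of the size-restricted
  catch, and
* a Gaussian GAM with identity link on the natural log of positive adjusted
  CPUE,

each with survey year as a categorical fixed factor, a bivariate tensor-product
smooth of (longitude, latitude), a univariate smooth of depth and a univariate
smooth of bottom temperature limited to a four-dimensional basis.  Smooths are
cubic B-splines with second-order difference penalties; the amount of smoothing
is chosen by minimizing generalized cross-validation (GCV),

    GCV(lambda) = n * D(lambda) / (n - edf(lambda))^2,

where D is the model deviance and edf the effective degrees of freedom
(trace of the influence matrix).  Binomial fits use penalized iteratively
reweighted least squares (PIRLS).

Estimators follow the scikit-learn protocol (``fit``/``predict``/
``get_params``) so they compose with ``sklearn.base.clone`` and model
selection; :func:`dredge_aic` runs the all-subsets AIC comparison over the
four candidate terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, clone

__all__ = [
    "PresenceGAM",
    "PositiveCpueGAM",
    "fit_presence",
    "fit_log_cpue",
    "predict_occurrence",
    "predict_abundance",
    "dredge_aic",
    "select_best",
    "CANDIDATE_TERMS",
]

CANDIDATE_TERMS = ("year", "lonlat", "depth", "temp")

_COVARIATE_COLUMNS = {
    "year": ("year",),
    "lonlat": ("lon", "lat"),
    "depth": ("depth_m",),
    "temp": ("temp_c",),
}


# ---------------------------------------------------------------------------
# basis machinery


def _make_knots(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Quantile-spaced interior knots with repeated boundary knots."""
    n_inner = df - degree - 1
    if n_inner < 0:
        raise ValueError(f"basis dimension {df} too small for degree {degree}")
    if n_inner > 0:
        qs = np.linspace(0.0, 1.0, n_inner + 2)[1:-1]
        inner = np.quantile(x, qs)
    else:
        inner = np.array([])
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("covariate has no spread; cannot build spline basis")
    return np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    # clip to the knot range: predictions are made at cell-mean covariates,
    # which lie inside the observed range up to numerical noise
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _sum_to_zero(basis: np.ndarray, penalty: np.ndarray):
    """Absorb the sum-to-zero constraint; returns (basis Z, Z' S Z, Z)."""
    c = basis.mean(axis=0)[None, :]
    _, _, vt = np.linalg.svd(c)
    z = vt[1:].T
    return basis @ z, z.T @ penalty @ z, z


@dataclass
class _SmoothState:
    """Frozen basis definition of one smooth term, reusable at predict time."""

    name: str
    knots: tuple[np.ndarray, ...]
    z: np.ndarray
    penalty: np.ndarray
    degree: int

    def design(self, X: pd.DataFrame) -> np.ndarray:
        cols = _COVARIATE_COLUMNS[self.name]
        mats = [
            _bspline_design(X[c].to_numpy(dtype=float), k, self.degree)
            for c, k in zip(cols, self.knots)
        ]
        raw = mats[0] if len(mats) == 1 else _row_kron(mats[0], mats[1])
        return raw @ self.z


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _build_smooth(name: str, X: pd.DataFrame, df, degree: int) -> _SmoothState:
    cols = _COVARIATE_COLUMNS[name]
    if len(cols) == 1:
        x = X[cols[0]].to_numpy(dtype=float)
        knots = (_make_knots(x, int(df), degree),)
        raw = _bspline_design(x, knots[0], degree)
        pen = _difference_penalty(raw.shape[1])
    else:
        k1, k2 = (int(d) for d in df)
        xs = [X[c].to_numpy(dtype=float) for c in cols]
        knots = tuple(_make_knots(x, k, degree) for x, k in zip(xs, (k1, k2)))
        b1 = _bspline_design(xs[0], knots[0], degree)
        b2 = _bspline_design(xs[1], knots[1], degree)
        raw = _row_kron(b1, b2)
        pen = np.kron(
            _difference_penalty(b1.shape[1]), np.eye(b2.shape[1])
        ) + np.kron(np.eye(b1.shape[1]), _difference_penalty(b2.shape[1]))
    _, pen_c, z = _sum_to_zero(raw, pen)
    return _SmoothState(name=name, knots=knots, z=z, penalty=pen_c, degree=degree)


# ---------------------------------------------------------------------------
# estimators


class _BaseGAM(BaseEstimator):
    """Shared machinery for both delta-model stages."""

    _family: str = ""

    def __init__(
        self,
        terms: tuple[str, ...] = CANDIDATE_TERMS,
        k_depth: int = 10,
        k_lonlat: tuple[int, int] = (6, 6),
        k_temp: int = 4,
        spline_degree: int = 3,
        log_lambda_bounds: tuple[float, float] = (-5.0, 8.0),
        max_gcv_evals: int = 200,
    ):
        self.terms = terms
        self.k_depth = k_depth
        self.k_lonlat = k_lonlat
        self.k_temp = k_temp
        self.spline_degree = spline_degree
        self.log_lambda_bounds = log_lambda_bounds
        self.max_gcv_evals = max_gcv_evals

    # -- design construction -------------------------------------------------
    def _validate_terms(self):
        unknown = set(self.terms) - set(CANDIDATE_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")

    def _required_columns(self):
        cols = set()
        for t in self.terms:
            cols.update(_COVARIATE_COLUMNS[t])
        return sorted(cols)

    def _check_covariates(self, X: pd.DataFrame):
        missing_cols = [c for c in self._required_columns() if c not in X.columns]
        if missing_cols:
            raise ValueError(f"missing covariate columns {missing_cols}")
        bad = X[self._required_columns()].isna().any(axis=1)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows have missing covariates; "
                "filter to complete cases before fitting"
            )

    def _build_design(self, X: pd.DataFrame):
        n = len(X)
        parts = [np.ones((n, 1))]
        if "year" in self.terms:
            self.years_ = tuple(sorted(pd.unique(X["year"])))
            for y in self.years_[1:]:
                parts.append((X["year"].to_numpy() == y).astype(float)[:, None])
        else:
            self.years_ = ()
        self.n_parametric_ = sum(p.shape[1] for p in parts)
        dfs = {"depth": self.k_depth, "lonlat": self.k_lonlat, "temp": self.k_temp}
        self.smooths_ = []
        blocks = []
        offset = self.n_parametric_
        for t in self.terms:
            if t == "year":
                continue
            st = _build_smooth(t, X, dfs[t], self.spline_degree)
            b = st.design(X)
            self.smooths_.append(st)
            blocks.append((offset, st.penalty))
            parts.append(b)
            offset += b.shape[1]
        self._penalty_blocks = blocks
        return np.hstack(parts)

    def _design_for(self, X: pd.DataFrame) -> np.ndarray:
        self._check_covariates(X)
        n = len(X)
        parts = [np.ones((n, 1))]
        if "year" in self.terms:
            seen = set(self.years_)
            unseen = sorted(set(pd.unique(X["year"])) - seen)
            if unseen:
                raise ValueError(f"year level(s) {unseen} not seen in training")
            for y in self.years_[1:]:
                parts.append((X["year"].to_numpy() == y).astype(float)[:, None])
        for st in self.smooths_:
            parts.append(st.design(X))
        return np.hstack(parts)

    def _embed_penalty(self, lambdas: np.ndarray, p: int) -> np.ndarray:
        pen = np.zeros((p, p))
        for lam, (off, s) in zip(lambdas, self._penalty_blocks):
            k = s.shape[0]
            pen[off : off + k, off : off + k] += lam * s
        return pen

    # -- fitting --------------------------------------------------------------
    def _solve(self, X, y, lambdas):
        """One penalized fit at fixed lambdas; family-specific."""
        raise NotImplementedError

    def _fit_common(self, X: pd.DataFrame, y: np.ndarray):
        self._validate_terms()
        self._check_covariates(X)
        Xd = self._build_design(X)
        n, p = Xd.shape
        if n <= p:
            raise ValueError(f"n = {n} rows but {p} design columns; need n > p")
        n_smooth = len(self._penalty_blocks)
        lo, hi = self.log_lambda_bounds

        def objective(loglams):
            lams = 10.0 ** np.clip(loglams, lo, hi)
            dev, edf = self._solve(Xd, y, lams)[1:3]
            return n * dev / (n - edf) ** 2

        if n_smooth:
            starts = [np.full(n_smooth, v) for v in (-1.0, 0.0, 1.0, 2.0, 3.0)]
            best = min(starts, key=objective)
            res = minimize(
                objective,
                best,
                method="Nelder-Mead",
                options=dict(xatol=0.05, fatol=1e-7, maxfev=self.max_gcv_evals),
            )
            loglams = np.clip(res.x, lo, hi)
        else:
            loglams = np.empty(0)
        lams = 10.0**loglams
        beta, dev, edf, extra = self._solve(Xd, y, lams)
        self.coef_ = beta
        self.lambda_ = lams
        self.edf_ = float(edf)
        self.deviance_ = float(dev)
        self.gcv_ = float(n * dev / (n - edf) ** 2)
        self.n_obs_ = n
        self._finalize(Xd, y, extra)
        # per-term effective df from the diagonal of the influence matrix
        diag = extra["edf_diag"]
        by_term = {"parametric": float(diag[: self.n_parametric_].sum())}
        off = self.n_parametric_
        for st in self.smooths_:
            k = st.penalty.shape[0]
            by_term[st.name] = float(diag[off : off + k].sum())
            off += k
        self.edf_by_term_ = by_term
        return self

    def _finalize(self, Xd, y, extra):
        raise NotImplementedError


class PresenceGAM(_BaseGAM):
    """Probability-of-occurrence stage: binomial GAM with a logit link.

    ``fit`` takes a covariate frame (columns ``year, lon, lat, depth_m,
    temp_c`` as required by ``terms``) and a binary presence vector;
    ``predict`` returns the occurrence probability PO in (0, 1).
    """

    _family = "binomial"

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("presence response must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "single response class (all present or all absent); "
                "the presence stage is not identifiable"
            )
        return self._fit_common(X, y)

    def _solve(self, X, y, lambdas, max_iter=40, tol=1e-8):
        n, p = X.shape
        pen = self._embed_penalty(lambdas, p)
        pbar = float(y.mean())
        eta = np.full(n, np.log(pbar / (1 - pbar)))
        dev_old = np.inf
        factor = None
        xtwx = None
        for _ in range(max_iter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            wx = X * w[:, None]
            xtwx = X.T @ wx
            a = xtwx + pen
            a[np.diag_indices_from(a)] += 1e-9 * (1 + np.abs(np.diag(a)))
            factor = cho_factor(a)
            beta = cho_solve(factor, wx.T @ z)
            eta = X @ beta
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
            dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
            if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
                break
            dev_old = dev
        edf_diag = np.diag(cho_solve(factor, xtwx))
        return beta, dev, float(edf_diag.sum()), {"edf_diag": edf_diag, "mu": mu}

    def _finalize(self, Xd, y, extra):
        mu = extra["mu"]
        self.fitted_ = mu
        self.loglik_ = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.edf_
        pbar = y.mean()
        null_dev = -2.0 * np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
        self.deviance_explained_ = 100.0 * (1.0 - self.deviance_ / null_dev)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Occurrence probability PO at the given covariates."""
        eta = self._design_for(X) @ self.coef_
        return np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)

    predict_proba = predict


class PositiveCpueGAM(_BaseGAM):
    """Positive-catch stage: Gaussian GAM on ln(adjusted CPUE).

    ``fit`` takes covariates and strictly positive CPUE values (the model is
    fit to their natural log); ``predict`` returns the back-transformed
    abundance PA = exp(ln-CPUE prediction).  No lognormal bias correction is
    applied: downstream standardization divides by a per-species statistic, so
    a constant multiplicative factor exp(sigma^2 / 2) cancels exactly.
    """

    _family = "gaussian"

    def fit(self, X: pd.DataFrame, cpue):
        cpue = np.asarray(cpue, dtype=float)
        if np.any(~np.isfinite(cpue)) or np.any(cpue <= 0):
            raise ValueError("positive-catch stage requires CPUE > 0 on all rows")
        return self._fit_common(X, np.log(cpue))

    def _solve(self, X, y, lambdas):
        n, p = X.shape
        pen = self._embed_penalty(lambdas, p)
        if not hasattr(self, "_xtx") or self._xtx.shape != (p, p):
            self._xtx = X.T @ X
            self._xty = X.T @ y
        a = self._xtx + pen
        a[np.diag_indices_from(a)] += 1e-9 * (1 + np.abs(np.diag(a)))
        factor = cho_factor(a)
        beta = cho_solve(factor, self._xty)
        resid = y - X @ beta
        rss = float(resid @ resid)
        edf_diag = np.diag(cho_solve(factor, self._xtx))
        return beta, rss, float(edf_diag.sum()), {"edf_diag": edf_diag}

    def _fit_common(self, X, y):
        self._xtx = np.empty((0, 0))  # reset cache per fit
        return super()._fit_common(X, y)

    def _finalize(self, Xd, y, extra):
        n = self.n_obs_
        rss = self.deviance_
        sigma2 = rss / n
        self.sigma_ = float(np.sqrt(rss / max(n - self.edf_, 1.0)))
        self.fitted_ = Xd @ self.coef_
        self.loglik_ = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        # +1 for the scale parameter in the AIC df accounting
        self.aic_ = -2.0 * self.loglik_ + 2.0 * (self.edf_ + 1.0)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.deviance_explained_ = 100.0 * (1.0 - rss / tss) if tss > 0 else 0.0
        del self._xtx, self._xty

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted positive abundance PA = exp(ln-CPUE prediction)."""
        return np.exp(self._design_for(X) @ self.coef_)

    def predict_log(self, X: pd.DataFrame) -> np.ndarray:
        return self._design_for(X) @ self.coef_


# ---------------------------------------------------------------------------
# functional wrappers


def fit_presence(data: pd.DataFrame, y, **params) -> PresenceGAM:
    """Fit the presence stage; thin wrapper over :class:`PresenceGAM`."""
    return PresenceGAM(**params).fit(data, y)


def fit_log_cpue(data: pd.DataFrame, cpue, **params) -> PositiveCpueGAM:
    """Fit the positive-catch stage; thin wrapper over :class:`PositiveCpueGAM`."""
    return PositiveCpueGAM(**params).fit(data, cpue)


def predict_occurrence(fit: PresenceGAM, covariates: pd.DataFrame) -> np.ndarray:
    return fit.predict(covariates)


def predict_abundance(fit: PositiveCpueGAM, covariates: pd.DataFrame) -> np.ndarray:
    return fit.predict(covariates)


# ---------------------------------------------------------------------------
# all-subsets AIC selection


def dredge_aic(
    estimator: _BaseGAM,
    X: pd.DataFrame,
    y,
    candidate_terms: tuple[str, ...] = CANDIDATE_TERMS,
) -> pd.DataFrame:
    """Fit every subset of ``candidate_terms`` (intercept always retained).

    Returns a model table sorted by AIC with one row per candidate: term
    inclusion flags, deviance explained (%), effective df, log-likelihood,
    delta-AIC and Akaike weights (normalized over the successful fits), and
    the GCV score.  A failed fit is recorded as a row with the error message,
    not raised.
    """
    rows = []
    fits = {}
    for r in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, r):
            est = clone(estimator)
            est.set_params(terms=subset)
            row = {t: t in subset for t in candidate_terms}
            row["terms"] = subset
            try:
                est.fit(X, y)
                row.update(
                    dev_expl_pct=est.deviance_explained_,
                    df=est.edf_,
                    loglik=est.loglik_,
                    aic=est.aic_,
                    gcv=est.gcv_,
                    error="",
                )
                fits[subset] = est
            except Exception as exc:  # recorded, not fatal
                row.update(
                    dev_expl_pct=np.nan, df=np.nan, loglik=np.nan,
                    aic=np.nan, gcv=np.nan, error=str(exc),
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["aic"].notna()
    table.loc[ok, "delta_aic"] = table.loc[ok, "aic"] - table.loc[ok, "aic"].min()
    rel = np.exp(-0.5 * table.loc[ok, "delta_aic"])
    table.loc[ok, "akaike_weight"] = rel / rel.sum()
    table = table.sort_values("aic", na_position="last").reset_index(drop=True)
    table.attrs["fits"] = fits
    table.attrs["candidate_terms"] = candidate_terms
    return table


def select_best(table: pd.DataFrame, policy: str = "min_aic") -> tuple[str, ...]:
    """Pick a model from a dredge table.

    ``min_aic`` returns the delta-AIC = 0 row.  ``force_full`` returns the
    full-term model regardless of its rank, the choice made for one response
    in the original analysis so that predictions stay consistent across
    species and stages.
    """
    if table.empty:
        raise ValueError("empty model table")
    if policy == "min_aic":
        ok = table[table["aic"].notna()]
        if ok.empty:
            raise ValueError("no successful fits in model table")
        return tuple(ok.iloc[0]["terms"])
    if policy == "force_full":
        cand = table.attrs.get("candidate_terms")
        if cand is None:
            cand = tuple(t for t in CANDIDATE_TERMS if t in table.columns)
        full = tuple(cand)
        match = table[table["terms"].apply(lambda t: tuple(t) == full)]
        if match.empty:
            raise ValueError("full model not present in table")
        return full
    raise ValueError(f"unknown policy {policy!r}")
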