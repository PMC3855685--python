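"""Single-season site-occupancy model with imperfect detection.

The model is the standard zero-inflated detection-history likelihood: a
site i is occupied with probability psi_i = expit(x_i' beta_psi); given
occupancy, each visit j yields a detection with probability
p_ij = expit(v_ij' beta_p); an all-zero history can arise either from an
occupied site never detected or from an unoccupied site:

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * I(sum_j y_ij = 0)

Maximisation is by quasi-Newton iteration with analytic gradients from
multiple deterministic starts; standard errors come from the inverse
observed information (finite-difference Hessian of the negative
log-likelihood at the optimum). Model comparison uses AICc with n = number
of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit

__all__ = [
    "DetectionData",
    "ModelSpec",
    "FittedModel",
    "negative_log_likelihood",
    "nll_gradient",
    "fit",
    "aicc",
    "standardize_covariates",
]


@dataclass
class DetectionData:
    """Sites x visits detection histories with site and visit covariates.

    ``y`` is an (n, J) float array with entries 0/1 and NaN for missing
    visits. ``visit_covariates`` maps a covariate name to an (n, J) array.
    """

    y: np.ndarray
    site_covariates: pd.DataFrame
    visit_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    site_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be a sites x visits matrix")
        ok = np.isnan(self.y) | (self.y == 0) | (self.y == 1)
        if not ok.all():
            raise ValueError("y entries must be 0, 1, or missing")
        if np.any(np.all(np.isnan(self.y), axis=1)):
            raise ValueError("every site needs at least one non-missing visit")
        if len(self.site_covariates) != self.n_sites:
            raise ValueError("site_covariates length must match y rows")
        for name, v in self.visit_covariates.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.y.shape:
                raise ValueError(f"visit covariate {name!r} shape mismatch")
            self.visit_covariates[name] = v

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    @property
    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection."""
        return float(np.nanmax(self.y, axis=1).mean())

    def subset(self, idx) -> "DetectionData":
        idx = np.asarray(idx)
        return DetectionData(
            y=self.y[idx],
            site_covariates=self.site_covariates.iloc[idx].reset_index(drop=True),
            visit_covariates={k: v[idx] for k, v in self.visit_covariates.items()},
            site_ids=[self.site_ids[i] for i in idx] if self.site_ids else None,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the occupancy and detection linear predictors.

    Intercepts are always included and not listed.
    """

    psi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi_terms", tuple(self.psi_terms))
        object.__setattr__(self, "p_terms", tuple(self.p_terms))
        for terms in (self.psi_terms, self.p_terms):
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate covariate names in {terms}")

    @property
    def n_params(self) -> int:
        return len(self.psi_terms) + len(self.p_terms) + 2

    @property
    def name(self) -> str:
        psi = "+".join(self.psi_terms) or "1"
        p = "+".join(self.p_terms) or "1"
        return f"psi({psi}) p({p})"


def _design_matrices(spec: ModelSpec, data: DetectionData):
    n, J = data.y.shape
    cols = [np.ones(n)]
    for t in spec.psi_terms:
        if t not in data.site_covariates.columns:
            raise KeyError(f"site covariate {t!r} not found")
        cols.append(data.site_covariates[t].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"occupancy design matrix for {spec.name} is rank deficient")

    vcols = [np.ones((n, J))]
    for t in spec.p_terms:
        if t not in data.visit_covariates:
            raise KeyError(f"visit covariate {t!r} not found")
        vcols.append(data.visit_covariates[t])
    V = np.stack(vcols, axis=-1)
    Vflat = V.reshape(n * J, -1)
    obs = ~np.isnan(data.y).reshape(-1)
    if np.linalg.matrix_rank(Vflat[obs]) < Vflat.shape[1]:
        raise ValueError(f"detection design matrix for {spec.name} is rank deficient")
    return X, V


def _site_loglik_parts(beta, X, V, y):
    """Per-site pieces of the likelihood, all on the log scale."""
    q = X.shape[1]
    bpsi, bp = beta[:q], beta[q:]
    eta_psi = X @ bpsi
    eta_p = V @ bp
    obs = ~np.isnan(y)
    ysafe = np.where(obs, y, 0.0)
    # y log p + (1-y) log(1-p), stable via log_expit
    terms = ysafe * log_expit(eta_p) + (1.0 - ysafe) * log_expit(-eta_p)
    log_cp = np.where(obs, terms, 0.0).sum(axis=1)
    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)
    detected = np.any(ysafe == 1, axis=1)
    return eta_psi, eta_p, obs, ysafe, log_cp, log_psi, log_1mpsi, detected


def negative_log_likelihood(
    beta: np.ndarray, spec: ModelSpec, data: DetectionData
) -> float:
    """Negative log-likelihood of the detection histories at ``beta``.

    ``beta`` concatenates the occupancy coefficients (intercept first) and
    the detection coefficients. Missing visits are skipped.
    """
    X, V = _design_matrices(spec, data)
    return _nll(np.asarray(beta, dtype=float), X, V, data.y)


def _nll(beta, X, V, y):
    _, _, _, _, log_cp, log_psi, log_1mpsi, detected = _site_loglik_parts(
        beta, X, V, y
    )
    occ_term = log_psi + log_cp
    ll = np.where(detected, occ_term, np.logaddexp(occ_term, log_1mpsi))
    return float(-ll.sum())


def _nll_grad(beta, X, V, y):
    q = X.shape[1]
    eta_psi, eta_p, obs, ysafe, log_cp, log_psi, log_1mpsi, detected = (
        _site_loglik_parts(beta, X, V, y)
    )
    psi = expit(eta_psi)
    p = expit(eta_p)
    # posterior probability the site is occupied
    w = np.where(detected, 1.0, expit((log_psi + log_cp) - log_1mpsi))
    g_psi = -(X.T @ (w - psi))
    resid = np.where(obs, ysafe - p, 0.0) * w[:, None]
    g_p = -np.einsum("nj,njk->k", resid, V)
    return np.concatenate([g_psi, g_p])


def nll_gradient(beta, spec: ModelSpec, data: DetectionData) -> np.ndarray:
    """Analytic gradient of the negative log-likelihood."""
    X, V = _design_matrices(spec, data)
    return _nll_grad(np.asarray(beta, dtype=float), X, V, data.y)


def aicc(logLik: float, K: int, n: int) -> float:
    """Small-sample AIC: -2 logLik + 2K + 2K(K+1)/(n - K - 1)."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * logLik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass
class FittedModel:
    """Maximum-likelihood fit of one ModelSpec."""

    spec: ModelSpec
    beta_psi: np.ndarray
    beta_p: np.ndarray
    se_psi: np.ndarray
    se_p: np.ndarray
    logLik: float
    K: int
    n_sites: int
    aicc: float
    converged: bool
    cov: np.ndarray | None = None

    @property
    def coefficients(self) -> dict[str, float]:
        out = {"psi_intercept": float(self.beta_psi[0])}
        out.update(
            {t: float(b) for t, b in zip(self.spec.psi_terms, self.beta_psi[1:])}
        )
        out["p_intercept"] = float(self.beta_p[0])
        out.update({t: float(b) for t, b in zip(self.spec.p_terms, self.beta_p[1:])})
        return out

    @property
    def standard_errors(self) -> dict[str, float]:
        out = {"psi_intercept": float(self.se_psi[0])}
        out.update({t: float(s) for t, s in zip(self.spec.psi_terms, self.se_psi[1:])})
        out["p_intercept"] = float(self.se_p[0])
        out.update({t: float(s) for t, s in zip(self.spec.p_terms, self.se_p[1:])})
        return out

    def predict_psi(self, site_covariates: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(site_covariates))]
            + [site_covariates[t].to_numpy(dtype=float) for t in self.spec.psi_terms]
        )
        return expit(X @ self.beta_psi)


def _fd_hessian(grad, x, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = x.size
    H = np.zeros((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (grad(xp) - grad(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def fit(
    spec: ModelSpec,
    data: DetectionData,
    n_starts: int = 5,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
    gtol: float = 1e-8,
) -> FittedModel:
    """Fit by L-BFGS-B from a zero start plus seeded random perturbations.

    The best optimum over all starts is reported. Wald standard errors use
    the inverse observed information; non-positive-definite information
    (typical under separation) yields inf standard errors rather than an
    error. ``converged`` is False only if every start failed.
    """
    X, V = _design_matrices(spec, data)
    y = data.y
    k = X.shape[1] + V.shape[2]
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    starts += [rng.normal(0.0, 0.5, k) for _ in range(max(0, n_starts - 1))]
    if warm_start is not None:
        starts.insert(0, np.asarray(warm_start, dtype=float))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            _nll, x0, args=(X, V, y), jac=_nll_grad, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res

    beta = best.x
    nll_val = float(best.fun)
    H = _fd_hessian(lambda b: _nll_grad(b, X, V, y), beta)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        se = np.where(diag > 0, np.sqrt(np.maximum(diag, 0.0)), np.inf)
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(k, np.inf)

    q = X.shape[1]
    n = data.n_sites
    ll = -nll_val
    return FittedModel(
        spec=spec,
        beta_psi=beta[:q],
        beta_p=beta[q:],
        se_psi=se[:q],
        se_p=se[q:],
        logLik=ll,
        K=k,
        n_sites=n,
        aicc=aicc(ll, k, n),
        converged=bool(any_success and np.isfinite(nll_val)),
        cov=cov,
    )


def standardize_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centre/scale columns to mean 0, sd 1; returns (scaled, means, sds)."""
    means = df.mean()
    sds = df.std(ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant covariate columns cannot be standardized: {bad}")
    return (df - means) / sds, means, sds
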