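"""All-subsets AICc model selection, averaging, variable importance, and
collinearity / overdispersion diagnostics.

Candidate models are every non-empty subset of the site (occupancy)
covariates crossed with every subset of the detection covariates —
detection-only models are excluded by construction, and the intercept-only
null model is appended for reference. Ranking uses AICc differences
(delta); models with delta <= 6 form the retained candidate set, over
which Akaike weights are renormalized. Model-averaged coefficients,
unconditional standard errors, and relative variable importance (RVI, the
summed weight of retained models containing a variable) are computed from
that set. Collinearity among site covariates is screened beforehand with
Belsley condition indices and variance-decomposition proportions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import DetectionData, FittedModel, ModelSpec, fit

__all__ = [
    "ModelSet",
    "AveragedEstimates",
    "FitDiagnostics",
    "BelsleyDiagnostics",
    "belsley_screen",
    "enumerate_models",
    "fit_candidates",
    "rank_and_weight",
    "model_average",
    "rvi",
    "overdispersion",
]


@dataclass
class ModelSet:
    """Ranked candidate models with AICc deltas and renormalized weights.

    ``table`` has one row per model: a ``model`` label, one column per
    covariate (NaN where the covariate is absent from that model),
    optional ``se_<term>`` columns, then df, logLik, AICc, delta, weight,
    retained. Weights are renormalized to sum to 1 over the retained
    (delta <= delta_max) models; non-retained rows carry weight 0.
    """

    table: pd.DataFrame
    term_columns: tuple[str, ...]
    delta_max: float
    fits: list[FittedModel] | None = None

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def membership(self, term: str) -> pd.Series:
        """Boolean: does each retained model include ``term``."""
        return self.retained[term].notna()


def rank_and_weight(models, delta_max: float = 6.0) -> ModelSet:
    """Rank models by AICc and compute renormalized Akaike weights.

    ``models`` is either a list of FittedModel (non-converged fits are
    dropped with a warning) or a prebuilt DataFrame with at least AICc and
    per-term coefficient columns (e.g. a published model table).
    """
    fits = None
    if isinstance(models, pd.DataFrame):
        table = models.copy()
        term_columns = tuple(
            c
            for c in table.columns
            if c
            not in ("model", "df", "logLik", "AICc", "delta", "weight", "retained")
            and not c.startswith("se_")
        )
    else:
        fits = [m for m in models if m.converged]
        dropped = len(models) - len(fits)
        if dropped:
            warnings.warn(f"{dropped} non-converged models excluded from ranking")
        if not fits:
            raise ValueError("no converged models to rank")
        term_columns = tuple(
            dict.fromkeys(
                t for m in fits for t in (*m.spec.psi_terms, *m.spec.p_terms)
            )
        )
        rows = []
        for m in fits:
            row: dict = {"model": m.spec.name}
            coefs = m.coefficients
            ses = m.standard_errors
            row["psi_intercept"] = coefs["psi_intercept"]
            row["p_intercept"] = coefs["p_intercept"]
            row["se_psi_intercept"] = ses["psi_intercept"]
            row["se_p_intercept"] = ses["p_intercept"]
            for t in term_columns:
                if t in coefs:
                    row[t] = coefs[t]
                    row[f"se_{t}"] = ses[t]
            row.update(df=m.K, logLik=m.logLik, AICc=m.aicc)
            rows.append(row)
        table = pd.DataFrame(rows)

    if "AICc" not in table.columns:
        raise ValueError("model table needs an AICc column")
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["retained"] = table["delta"] <= delta_max
    raw = np.exp(-0.5 * table["delta"])
    total = raw[table["retained"]].sum()
    table["weight"] = np.where(table["retained"], raw / total, 0.0)
    table = table.sort_values("delta", kind="stable").reset_index(drop=True)
    return ModelSet(
        table=table, term_columns=term_columns, delta_max=delta_max, fits=fits
    )


def enumerate_models(
    site_covs: list[str], det_covs: list[str], include_null: bool = True
) -> list[ModelSpec]:
    """All non-empty site-covariate subsets crossed with all detection
    subsets; the intercept-only null model is appended last for reference.
    """
    if len(set(site_covs)) != len(site_covs) or len(set(det_covs)) != len(det_covs):
        raise ValueError("duplicate covariate names")
    if set(site_covs) & set(det_covs):
        raise ValueError("site and detection covariate names must not overlap")
    if not site_covs:
        raise ValueError("need at least one site covariate")
    specs = []
    for k in range(1, len(site_covs) + 1):
        for psi in itertools.combinations(site_covs, k):
            for d in range(0, len(det_covs) + 1):
                for p in itertools.combinations(det_covs, d):
                    specs.append(ModelSpec(psi_terms=psi, p_terms=p))
    if include_null:
        specs.append(ModelSpec(psi_terms=(), p_terms=()))
    return specs


def fit_candidates(
    specs: list[ModelSpec],
    data: DetectionData,
    seed: int = 0,
    n_starts: int = 3,
) -> list[FittedModel]:
    """Fit every candidate spec; fit failures become non-converged entries."""
    return [fit(s, data, n_starts=n_starts, seed=seed) for s in specs]


@dataclass
class AveragedEstimates:
    """Model-averaged coefficients with unconditional SEs and RVI."""

    estimates: pd.DataFrame  # index: term; columns: estimate, se, ci_lo, ci_hi, rvi
    mode: str  # "full" or "conditional"

    def __getitem__(self, term: str) -> float:
        return float(self.estimates.loc[term, "estimate"])


def model_average(mset: ModelSet, mode: str = "conditional") -> AveragedEstimates:
    """Average coefficients over the retained set.

    full: absent terms contribute 0, beta_bar = sum w_i beta_i over all
    retained models; conditional: weights renormalized over the models
    containing the term. Unconditional SE follows Burnham & Anderson:
    sqrt(sum w_i (se_i^2 + (beta_i - beta_bar)^2)) over the same model
    set (NaN when per-model SEs are unavailable, e.g. printed tables).
    """
    if mode not in ("full", "conditional"):
        raise ValueError("mode must be 'full' or 'conditional'")
    ret = mset.retained
    w = ret["weight"].to_numpy()
    rows = {}
    for term in mset.term_columns:
        beta = ret[term].to_numpy(dtype=float) if term in ret else np.full(len(ret), np.nan)
        has = ~np.isnan(beta)
        if not has.any():
            raise ValueError(f"term {term!r} absent from every retained model")
        se_col = f"se_{term}"
        se = ret[se_col].to_numpy(dtype=float) if se_col in ret else np.full(len(ret), np.nan)
        rvi_t = float(w[has].sum())
        if mode == "full":
            b = np.where(has, beta, 0.0)
            s = np.where(has, se, 0.0)
            wt = w
            est = float(np.sum(wt * b))
        else:
            b = beta[has]
            s = se[has]
            wt = w[has] / w[has].sum()
            est = float(np.sum(wt * b))
        if np.all(np.isnan(s) | (s == 0)) and np.any(np.isnan(s)):
            unc_se = math.nan
        else:
            unc_se = float(np.sqrt(np.sum(wt * (s**2 + (b - est) ** 2))))
        rows[term] = {
            "estimate": est,
            "se": unc_se,
            "ci_lo": est - 1.96 * unc_se,
            "ci_hi": est + 1.96 * unc_se,
            "rvi": rvi_t,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "term"
    return AveragedEstimates(estimates=df, mode=mode)


def rvi(mset: ModelSet) -> pd.Series:
    """Relative variable importance: summed weight of retained models
    whose occupancy or detection terms include the variable."""
    ret = mset.retained
    out = {
        term: float(ret.loc[ret[term].notna(), "weight"].sum())
        if term in ret
        else 0.0
        for term in mset.term_columns
    }
    s = pd.Series(out, name="rvi")
    s.index.name = "term"
    return s


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class FitDiagnostics:
    """Overdispersion check: deviance against the saturated model."""

    deviance: float
    rdof: int
    c_hat: float
    logLik_saturated: float
    logLik_model: float
    assessment: str
    saturated_definition: str = "per-site saturated (free psi_i, p_i per site)"


def overdispersion(
    global_fit: FittedModel, data: DetectionData, saturated: str = "site"
) -> FitDiagnostics:
    """c_hat = deviance / (n - p) for the global model.

    deviance = 2 (logLik_sat - logLik_model). Two saturated-model
    definitions are available:

    * ``"site"`` (default): each site gets free (psi_i, p_i); a pure
      history (all 0 or all 1 over J_i observed visits) has saturated
      likelihood 1, a mixed history with d detections has
      (d/J_i)^d (1 - d/J_i)^(J_i - d). This dominates every covariate
      model, so the deviance is non-negative.
    * ``"pooled"``: multinomial over pooled observed detection-history
      patterns, sum_h n_h ln(n_h / N). Appropriate only when comparing
      against models without site-specific covariates.

    c_hat near 1 indicates adequate fit; values above ~4 indicate
    overdispersion. The definition used is recorded in the output.
    """
    n = data.n_sites
    p = global_fit.K
    if n <= p:
        raise ValueError("residual degrees of freedom must be positive")
    if saturated == "site":
        ll_sat = 0.0
        for row in data.y:
            obs = row[~np.isnan(row)]
            d, J_i = obs.sum(), obs.size
            if 0 < d < J_i:
                phat = d / J_i
                ll_sat += d * math.log(phat) + (J_i - d) * math.log(1 - phat)
        definition = FitDiagnostics.saturated_definition
    elif saturated == "pooled":
        patterns: dict[tuple, int] = {}
        for row in data.y:
            key = tuple("m" if np.isnan(v) else int(v) for v in row)
            patterns[key] = patterns.get(key, 0) + 1
        ll_sat = sum(c * math.log(c / n) for c in patterns.values())
        definition = "multinomial over pooled observed detection-history patterns"
    else:
        raise ValueError("saturated must be 'site' or 'pooled'")
    deviance = 2.0 * (ll_sat - global_fit.logLik)
    rdof = n - p
    c_hat = deviance / rdof
    if c_hat <= 0:
        assessment = "degenerate"
    elif c_hat < 2:
        assessment = "adequate"
    elif c_hat <= 4:
        assessment = "moderate overdispersion"
    else:
        assessment = "overdispersed"
    return FitDiagnostics(
        deviance=deviance,
        rdof=rdof,
        c_hat=c_hat,
        logLik_saturated=ll_sat,
        logLik_model=global_fit.logLik,
        assessment=assessment,
        saturated_definition=definition,
    )


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass
class BelsleyDiagnostics:
    """One screening pass: condition indices and VDP matrix."""

    columns: tuple[str, ...]
    condition_indices: np.ndarray  # per SVD component, descending singular value
    vdp: pd.DataFrame  # components x covariates
    flagged: list[str] = field(default_factory=list)


def _belsley_pass(X: pd.DataFrame) -> BelsleyDiagnostics:
    cols = tuple(X.columns)
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-length covariate column")
    A = A / norms
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    s_floor = np.maximum(s, np.finfo(float).tiny)
    ci = s[0] / s_floor
    ci[s == 0] = np.inf
    # variance shares of each coefficient across components
    phi = (Vt**2) / (s_floor**2)[:, None]
    pi = phi / phi.sum(axis=0, keepdims=True)
    vdp = pd.DataFrame(pi, columns=cols)
    return BelsleyDiagnostics(columns=cols, condition_indices=ci, vdp=vdp)


def belsley_screen(
    X: pd.DataFrame,
    ci_threshold: float = 30.0,
    vdp_threshold: float = 0.5,
) -> tuple[list[str], list[BelsleyDiagnostics]]:
    """Iteratively drop covariates implicated in near-dependencies.

    Per pass: columns are scaled to unit length and decomposed by SVD;
    condition indices are max(singular value)/singular value; a component
    with condition index above ``ci_threshold`` in which two or more
    covariates have variance-decomposition proportion at or above
    ``vdp_threshold`` marks those covariates as involved in a
    near-dependency. The flagged covariate with the largest VDP is dropped
    and the pass repeats until nothing is flagged. Returns the retained
    column names and the per-pass diagnostics.
    """
    X = X.copy()
    history: list[BelsleyDiagnostics] = []
    tol = 1e-9
    while X.shape[1] >= 2:
        diag = _belsley_pass(X)
        bad_components = np.nonzero(diag.condition_indices > ci_threshold)[0]
        flagged: dict[str, float] = {}
        for k in bad_components:
            row = diag.vdp.iloc[k]
            involved = row[row >= vdp_threshold - tol]
            if len(involved) >= 2:
                for name, v in involved.items():
                    flagged[name] = max(flagged.get(name, 0.0), float(v))
        diag.flagged = sorted(flagged, key=flagged.get, reverse=True)
        history.append(diag)
        if not flagged:
            break
        drop = diag.flagged[0]
        X = X.drop(columns=[drop])
    else:
        if X.shape[1] < 2:
            history.append(_belsley_pass(X) if X.shape[1] else None)
    return list(X.columns), [h for h in history if h is not None]
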