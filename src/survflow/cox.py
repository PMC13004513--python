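"""Cox proportional-hazards regression by maximum partial likelihood.

The hazard model is h(t | x) = h0(t) * exp(beta' x). Coefficients are found
by Newton-Raphson on the log partial likelihood, starting from beta = 0, with
step-halving whenever a step would decrease the objective. Tied event times
are handled by Efron's correction (default) or Breslow's; the two coincide
when no event times are tied. Covariates are mean-centered internally for
numerical stability; reported coefficients are on the original scale and the
centering constants are stored for prediction.

The baseline cumulative hazard H0(t) is the Breslow estimator computed with
the centered linear predictor, so an individual survival prediction is
S(t | x) = exp(-H0(t) * exp(eta)) with eta = beta' (x - xbar).

Separation (monotone likelihood) is detected when a coefficient exceeds a
magnitude cap while the gradient has not vanished; the fit is returned with
``converged=False`` and a warning rather than raising, because small
exploratory cohorts hit this routinely during feature screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .errors import (
    CollinearityError,
    DegenerateFeatureError,
    NoEventsError,
    ParseError,
    SchemaError,
)

__all__ = [
    "CoxModel",
    "cox_fit",
    "cox_score_test",
    "hazard_ratio_table",
    "predict_linear",
    "predict_survival",
    "model_to_dict",
    "model_from_dict",
]

_MAX_ITER = 100
_TOL_STEP = 1e-9
_TOL_LL = 1e-12
_MAX_HALVINGS = 20
_SEPARATION_CAP = 20.0


@dataclass(frozen=True)
class CoxModel:
    """A fitted proportional-hazards model with inference and baseline hazard."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    hr_ci_lower: np.ndarray
    hr_ci_upper: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood_null: float
    log_partial_likelihood_fit: float
    lrt_statistic: float
    lrt_p: float
    baseline_times: np.ndarray
    baseline_cumulative_hazard: np.ndarray
    covariate_means: np.ndarray
    ties_method: str
    confidence_level: float
    converged: bool
    iterations: int
    n: int
    n_events: int
    warnings: tuple[str, ...] = ()


class _PartialLikelihood:
    """Precomputed risk-set structure for one (times, events) layout.

    Building this once and reusing it across features makes univariate
    screening of thousands of features cheap: only the covariate column is
    re-sorted per feature.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=np.int8)
        if events.sum() == 0:
            raise NoEventsError("Cox fit requires at least one event")
        self.n = len(times)
        self.order = np.argsort(times, kind="stable")
        self.t = times[self.order]
        self.e = events[self.order]
        self.event_rows = np.flatnonzero(self.e == 1)
        self.uet = np.unique(self.t[self.event_rows])  # distinct event times
        self.first_idx = np.searchsorted(self.t, self.uet, side="left")
        # map each event row to its distinct-event-time index
        self.evt_group = np.searchsorted(self.uet, self.t[self.event_rows])
        self.d = np.bincount(self.evt_group, minlength=len(self.uet)).astype(float)
        self.tied_groups = np.flatnonzero(self.d >= 2)

    def loglik_grad_info(self, X: np.ndarray, beta: np.ndarray, ties: str):
        """Log partial likelihood, gradient and observed information at beta.

        X must already be sorted by self.order.
        """
        m = len(self.uet)
        p = X.shape[1]
        eta = X @ beta
        shift = eta.max() if eta.size else 0.0
        w = np.exp(eta - shift)
        xw = X * w[:, None]

        # reverse cumulative sums -> risk-set aggregates at each event time
        rw = np.cumsum(w[::-1])[::-1]
        rxw = np.cumsum(xw[::-1], axis=0)[::-1]
        outer = X[:, :, None] * xw[:, None, :]
        rxxw = np.cumsum(outer[::-1], axis=0)[::-1]

        R = rw[self.first_idx]  # (m,)
        S1 = rxw[self.first_idx]  # (m, p)
        S2 = rxxw[self.first_idx]  # (m, p, p)

        # l = 0 term (shared by Breslow and Efron)
        mu = S1 / R[:, None]
        ll = float(eta[self.event_rows].sum() - self.d @ (np.log(R) + shift))
        grad = X[self.event_rows].sum(axis=0) - self.d @ mu
        info = np.einsum("j,jab->ab", self.d / R, S2) - np.einsum(
            "j,ja,jb->ab", self.d, mu, mu
        )

        if ties == "efron" and self.tied_groups.size:
            # tied-event aggregates
            E = np.zeros(m)
            E1 = np.zeros((m, p))
            E2 = np.zeros((m, p, p))
            np.add.at(E, self.evt_group, w[self.event_rows])
            np.add.at(E1, self.evt_group, xw[self.event_rows])
            np.add.at(E2, self.evt_group, outer[self.event_rows])
            for j in self.tied_groups:
                dj = int(self.d[j])
                # replace the Breslow contribution of this group by Efron's
                ll += dj * (np.log(R[j]) + shift)
                grad += dj * mu[j]
                info -= dj * (S2[j] / R[j] - np.outer(mu[j], mu[j]))
                for l in range(dj):
                    f = l / dj
                    denom = R[j] - f * E[j]
                    num = S1[j] - f * E1[j]
                    muj = num / denom
                    ll -= np.log(denom) + shift
                    grad -= muj
                    info += (S2[j] - f * E2[j]) / denom - np.outer(muj, muj)
        return ll, grad, info


def _prepare(dataset: SurvivalDataset, features):
    names = tuple(features) if features is not None else dataset.feature_names
    sub = dataset.select_features(names) if names != dataset.feature_names else dataset
    X = sub.covariates
    # complete-case subsetting on the features in use, with a reported count
    ok = np.isfinite(X).all(axis=1)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} incomplete cases (missing covariate values)",
            UserWarning,
            stacklevel=3,
        )
        sub = sub.subset(ok)
        X = sub.covariates
    for j, name in enumerate(names):
        if np.unique(X[:, j]).size <= 1:
            raise DegenerateFeatureError(f"feature {name!r} is constant")
    return sub, names


def cox_fit(
    dataset: SurvivalDataset,
    features=None,
    ties_method: str = "efron",
    confidence_level: float = 0.95,
) -> CoxModel:
    """Fit a Cox proportional-hazards model on the selected features.

    Parameters
    ----------
    features : subset of dataset.feature_names (default: all)
    ties_method : 'efron' (default) or 'breslow'
    confidence_level : level for hazard-ratio confidence intervals
    """
    if ties_method not in ("efron", "breslow"):
        raise ParseError(f"unknown ties method {ties_method!r}")
    sub, names = _prepare(dataset, features)
    means = sub.covariates.mean(axis=0)
    pl = _PartialLikelihood(sub.time, sub.event)
    Xc = (sub.covariates - means)[pl.order]
    p = Xc.shape[1]

    beta = np.zeros(p)
    ll, grad, info = pl.loglik_grad_info(Xc, beta, ties_method)
    ll_null = ll
    notes: list[str] = []
    converged = False
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                "singular information matrix; features "
                f"{list(names)} are collinear or carry no events"
            ) from None
        # step-halving: never accept a step that decreases the objective
        scale = 1.0
        for _ in range(_MAX_HALVINGS + 1):
            cand = beta + scale * step
            ll_new, grad_new, info_new = pl.loglik_grad_info(Xc, cand, ties_method)
            if ll_new >= ll - 1e-14:
                break
            scale /= 2
        delta = np.abs(cand - beta).max()
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if delta < _TOL_STEP or rel < _TOL_LL:
            converged = True
            break
        if np.abs(beta).max() > _SEPARATION_CAP and np.abs(grad).max() > 1e-4:
            notes.append(
                "monotone partial likelihood (separation): |beta| exceeds "
                f"{_SEPARATION_CAP}; estimates diverge"
            )
            warnings.warn(notes[-1], UserWarning, stacklevel=2)
            converged = False
            break
    else:
        notes.append(f"no convergence within {_MAX_ITER} iterations")

    if np.abs(beta).max() > _SEPARATION_CAP:
        # the likelihood plateau of a monotone (separated) fit also satisfies
        # the gradient tolerance, so the magnitude cap is checked on exit too
        j = int(np.abs(beta).argmax())
        notes.append(
            f"monotone partial likelihood (separation) suspected: |beta| for "
            f"{names[j]!r} exceeds {_SEPARATION_CAP}; estimate unreliable"
        )
        warnings.warn(notes[-1], UserWarning, stacklevel=2)
        converged = False

    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        raise CollinearityError(
            f"near-singular information matrix (condition number {cond:.2e}); "
            f"features {list(names)} are collinear"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + confidence_level / 2)
    wald_z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(wald_z))
    lrt = max(2 * (ll - ll_null), 0.0)

    # Breslow baseline cumulative hazard on the centered linear predictor
    eta = Xc @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    rw = np.cumsum(w[::-1])[::-1]
    dH = pl.d / (rw[pl.first_idx] * np.exp(shift))
    H0 = np.cumsum(dH)

    with np.errstate(over="ignore"):  # separated fits can overflow exp(beta)
        hr = np.exp(beta)
        hr_lo = np.exp(beta - z * se)
        hr_hi = np.exp(beta + z * se)
    return CoxModel(
        feature_names=names,
        coefficients=beta,
        standard_errors=se,
        hazard_ratios=hr,
        hr_ci_lower=hr_lo,
        hr_ci_upper=hr_hi,
        wald_z=wald_z,
        wald_p=wald_p,
        log_partial_likelihood_null=ll_null,
        log_partial_likelihood_fit=ll,
        lrt_statistic=lrt,
        lrt_p=float(stats.chi2.sf(lrt, p)),
        baseline_times=pl.uet.copy(),
        baseline_cumulative_hazard=H0,
        covariate_means=means,
        ties_method=ties_method,
        confidence_level=confidence_level,
        converged=converged,
        iterations=iterations,
        n=sub.n,
        n_events=sub.n_events,
        warnings=tuple(notes),
    )


def cox_score_test(
    dataset: SurvivalDataset, features=None, ties_method: str = "breslow"
) -> tuple[float, int, float]:
    """Score (Rao) test of beta = 0: returns (chi_square, df, p_value).

    With a single binary group indicator and no tied event times this equals
    the two-group log-rank chi-square.
    """
    sub, names = _prepare(dataset, features)
    means = sub.covariates.mean(axis=0)
    pl = _PartialLikelihood(sub.time, sub.event)
    Xc = (sub.covariates - means)[pl.order]
    _, grad, info = pl.loglik_grad_info(Xc, np.zeros(Xc.shape[1]), ties_method)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = Xc.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))


def hazard_ratio_table(model: CoxModel):
    """Per-covariate hazard ratios with CIs and Wald tests, in input order."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": list(model.feature_names),
            "beta": model.coefficients,
            "se": model.standard_errors,
            "hr": model.hazard_ratios,
            "hr_ci_lower": model.hr_ci_lower,
            "hr_ci_upper": model.hr_ci_upper,
            "wald_z": model.wald_z,
            "wald_p": model.wald_p,
        }
    )


def _check_covariates(model: CoxModel, covariates: np.ndarray) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} covariate columns, got {X.shape[1]}"
        )
    return X


def predict_linear(model: CoxModel, covariates: np.ndarray) -> np.ndarray:
    """Risk score eta = beta' (x - xbar) per subject (higher = higher risk)."""
    X = _check_covariates(model, covariates)
    return (X - model.covariate_means) @ model.coefficients


def baseline_hazard_at(model: CoxModel, t: np.ndarray) -> np.ndarray:
    """Right-continuous lookup of H0(t); H0 = 0 before the first event time."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if (t < 0).any():
        raise ParseError("negative horizon")
    idx = np.searchsorted(model.baseline_times, t, side="right") - 1
    H = np.where(idx >= 0, model.baseline_cumulative_hazard[np.maximum(idx, 0)], 0.0)
    return H


def predict_survival(
    model: CoxModel, covariates: np.ndarray, horizons
) -> np.ndarray:
    """S(t | x) = exp(-H0(t) exp(eta)) for each subject (rows) and horizon
    (columns)."""
    eta = predict_linear(model, covariates)
    H = baseline_hazard_at(model, horizons)
    return np.exp(-np.outer(np.exp(eta), H))


def model_to_dict(model: CoxModel) -> dict:
    """JSON-serializable dict with every field needed to reload the model."""
    return {
        "feature_names": list(model.feature_names),
        "coefficients": model.coefficients.tolist(),
        "standard_errors": model.standard_errors.tolist(),
        "hazard_ratios": model.hazard_ratios.tolist(),
        "hr_ci_lower": model.hr_ci_lower.tolist(),
        "hr_ci_upper": model.hr_ci_upper.tolist(),
        "wald_z": model.wald_z.tolist(),
        "wald_p": model.wald_p.tolist(),
        "log_partial_likelihood_null": model.log_partial_likelihood_null,
        "log_partial_likelihood_fit": model.log_partial_likelihood_fit,
        "lrt_statistic": model.lrt_statistic,
        "lrt_p": model.lrt_p,
        "baseline_times": model.baseline_times.tolist(),
        "baseline_cumulative_hazard": model.baseline_cumulative_hazard.tolist(),
        "covariate_means": model.covariate_means.tolist(),
        "ties_method": model.ties_method,
        "confidence_level": model.confidence_level,
        "converged": model.converged,
        "iterations": model.iterations,
        "n": model.n,
        "n_events": model.n_events,
        "warnings": list(model.warnings),
    }


def model_from_dict(d: dict) -> CoxModel:
    """Inverse of :func:`model_to_dict`."""
    return CoxModel(
        feature_names=tuple(d["feature_names"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        standard_errors=np.asarray(d["standard_errors"], dtype=float),
        hazard_ratios=np.asarray(d["hazard_ratios"], dtype=float),
        hr_ci_lower=np.asarray(d["hr_ci_lower"], dtype=float),
        hr_ci_upper=np.asarray(d["hr_ci_upper"], dtype=float),
        wald_z=np.asarray(d["wald_z"], dtype=float),
        wald_p=np.asarray(d["wald_p"], dtype=float),
        log_partial_likelihood_null=float(d["log_partial_likelihood_null"]),
        log_partial_likelihood_fit=float(d["log_partial_likelihood_fit"]),
        lrt_statistic=float(d["lrt_statistic"]),
        lrt_p=float(d["lrt_p"]),
        baseline_times=np.asarray(d["baseline_times"], dtype=float),
        baseline_cumulative_hazard=np.asarray(
            d["baseline_cumulative_hazard"], dtype=float
        ),
        covariate_means=np.asarray(d["covariate_means"], dtype=float),
        ties_method=str(d["ties_method"]),
        confidence_level=float(d["confidence_level"]),
        converged=bool(d["converged"]),
        iterations=int(d["iterations"]),
        n=int(d["n"]),
        n_events=int(d["n_events"]),
        warnings=tuple(d.get("warnings", ())),
    )
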