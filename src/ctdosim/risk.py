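"""Excess-relative-risk dose-response fitting.

The disease model is a stratified Poisson rate model
``rate = lambda_0(stratum) * (1 + beta * D)`` with D the organ dose in Gy
and beta the excess relative risk per Gy. Stratum baselines are profiled
out analytically (the MLE of each baseline given beta is
cases_s / sum_{i in s} PY_i (1 + beta D_i)), leaving a one-dimensional
profile log-likelihood that is maximized numerically; 95% confidence
limits come from the chi-square(1) profile-likelihood cutoff.

Dose enters in Gy; cohort dose realizations are produced in mGy, and the
conversion is explicit at this module's boundary (`REALIZATION_DOSE_SCALE`).

Two strategies fit a dose response over multiple cohort dose
realizations: the per-patient mean dose, or all realizations fitted
separately and combined with likelihood weights
(w_v ∝ exp(l_v - max l)); the combined interval is read off the
weighted mixture of the per-realization profile distributions, so
between-realization spread (shared dosimetry error) widens it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .uncertainty import RealizationSet

__all__ = ["OutcomeTable", "ErrFit", "fit_err", "fit_mean_dose",
           "fit_all_realizations", "REALIZATION_DOSE_SCALE"]

REALIZATION_DOSE_SCALE = 1e-3  # realization doses are mGy; the model wants Gy
_CHI2_95 = 3.841458820694124  # chi-square(1) 95% quantile
_BOUND_MARGIN = 1e-6


@dataclass
class OutcomeTable:
    """Per-patient outcomes: person-years, case counts and strata."""

    frame: pd.DataFrame  # columns: patient_id, person_years, cases, stratum

    def __post_init__(self):
        need = {"patient_id", "person_years", "cases", "stratum"}
        if not need <= set(self.frame.columns):
            raise ValidationError(f"outcome table needs columns {sorted(need)}")
        if (self.frame["person_years"] <= 0).any():
            raise ValidationError("person-years must be positive")
        if (self.frame["cases"] < 0).any():
            raise ValidationError("case counts must be non-negative")

    def aligned(self, patient_ids: list[str]) -> "OutcomeTable":
        df = self.frame.set_index("patient_id").loc[list(patient_ids)].reset_index()
        return OutcomeTable(df)


@dataclass
class ErrFit:
    """One excess-relative-risk fit."""

    beta: float  # ERR per Gy
    ci: tuple[float, float]
    loglik: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    realization: int | str = "single"
    n_excluded: int = 0
    per_realization: list["ErrFit"] | None = None

    def __post_init__(self):
        if self.converged and not self.ci[0] <= self.beta <= self.ci[1]:
            raise ValidationError("confidence interval must contain the estimate")


def _profile_loglik(beta: float, dose: np.ndarray, cases: np.ndarray,
                    py: np.ndarray, strata: np.ndarray,
                    stratum_ids: np.ndarray) -> float:
    rr = 1.0 + beta * dose
    if np.any(rr <= 0):
        return -np.inf
    ll = float(np.sum(cases * np.log(rr)))
    t = np.bincount(strata, weights=py * rr, minlength=len(stratum_ids))
    c = np.bincount(strata, weights=cases, minlength=len(stratum_ids))
    pos = c > 0
    ll -= float(np.sum(c[pos] * np.log(t[pos])))
    return ll


def fit_err(dose_gy: np.ndarray, outcomes: OutcomeTable,
            realization: int | str = "single") -> ErrFit:
    """Maximum-likelihood ERR fit of one dose vector.

    Non-convergence and boundary solutions are flagged on the returned
    fit, never raised.
    """
    dose = np.asarray(dose_gy, float)
    if np.any(dose < 0):
        raise ValidationError("doses must be non-negative")
    df = outcomes.frame
    if len(df) != len(dose):
        raise ValidationError("dose vector and outcome table lengths differ")
    cases = df["cases"].to_numpy(float)
    py = df["person_years"].to_numpy(float)
    stratum_ids, strata = np.unique(df["stratum"].to_numpy(), return_inverse=True)

    dmax = dose.max()
    if dmax <= 0 or np.ptp(dose) == 0:
        return ErrFit(0.0, (-np.inf, np.inf), 0.0, False,
                      flags=["degenerate: no dose contrast"],
                      realization=realization)
    lb = -1.0 / dmax * (1.0 - _BOUND_MARGIN)
    if cases.sum() == 0:
        ll = _profile_loglik(lb, dose, cases, py, strata, stratum_ids)
        return ErrFit(lb, (lb, np.inf), ll, False,
                      flags=["boundary: no cases observed"],
                      realization=realization)

    def nll(b):
        return -_profile_loglik(b, dose, cases, py, strata, stratum_ids)

    ub = 1e4 / dmax
    res = optimize.minimize_scalar(nll, bounds=(lb, ub), method="bounded",
                                   options={"xatol": 1e-8 / dmax})
    beta = float(res.x)
    llmax = -float(res.fun)
    flags = []
    converged = bool(res.success) and np.isfinite(llmax)
    if beta <= lb * (1 - 1e-6) + 1e-12 or abs(beta - lb) < 1e-8 / dmax:
        flags.append("boundary: lower")
    cut = llmax - _CHI2_95 / 2

    def diff(b):
        return _profile_loglik(b, dose, cases, py, strata, stratum_ids) - cut

    lo = lb
    if diff(lb) < 0:
        lo = optimize.brentq(diff, lb, beta, xtol=1e-10 / max(dmax, 1e-12))
    else:
        flags.append("ci-lower at boundary")
    hi_probe = beta if beta > 0 else 1.0 / dmax
    while diff(hi_probe) > 0 and hi_probe < 1e8 / dmax:
        hi_probe *= 4
    if diff(hi_probe) <= 0:
        hi = optimize.brentq(diff, max(beta, lb + 1e-12), hi_probe,
                             xtol=1e-10 / max(dmax, 1e-12))
    else:
        hi = np.inf
        flags.append("ci-upper unbounded")
    return ErrFit(beta, (float(lo), float(hi)), llmax, converged,
                  flags=flags, realization=realization)


def fit_mean_dose(rs: RealizationSet, outcomes: OutcomeTable, organ: str) -> ErrFit:
    """ERR fit of the per-patient mean dose over all realizations."""
    out = outcomes.aligned(rs.patient_ids)
    dose = rs.mean_dose(organ) * REALIZATION_DOSE_SCALE
    fit = fit_err(dose, out, realization="mean")
    return fit


def fit_all_realizations(rs: RealizationSet, outcomes: OutcomeTable, organ: str,
                         weight_fn=None) -> ErrFit:
    """Fit every realization; combine with likelihood weights.

    The combined estimate is the weighted mean of the per-realization
    estimates with weights ∝ exp(l_v - max l) (``weight_fn`` may replace
    this rule); the combined interval is the 2.5/97.5 percentile band of
    the weighted mixture of per-realization profile distributions.
    Non-converged realizations are excluded and counted.
    """
    if rs.v < 2:
        raise ValidationError("all-realizations fitting requires V >= 2")
    out = outcomes.aligned(rs.patient_ids)
    oi = rs.organ_index(organ)
    fits = [fit_err(rs.doses[v, :, oi] * REALIZATION_DOSE_SCALE, out, realization=v)
            for v in range(rs.v)]
    good = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(good)
    if not good:
        return ErrFit(np.nan, (np.nan, np.nan), -np.inf, False,
                      flags=["no converged realization"], realization="combined",
                      n_excluded=n_excluded, per_realization=fits)
    ll = np.array([f.loglik for f in good])
    if weight_fn is None:
        w = np.exp(ll - ll.max())
    else:
        w = np.asarray(weight_fn(good), float)
    w = w / w.sum()
    beta = float(np.sum(w * [f.beta for f in good]))

    # mixture of profile distributions on a common grid
    df = out.frame
    cases = df["cases"].to_numpy(float)
    py = df["person_years"].to_numpy(float)
    stratum_ids, strata = np.unique(df["stratum"].to_numpy(), return_inverse=True)
    lo = min(f.ci[0] for f in good)
    finite_uppers = [f.ci[1] for f in good if np.isfinite(f.ci[1])]
    if not finite_uppers:
        # every realization's profile is flat on the right; the mixture
        # percentile interval is improper, so report the unbounded interval
        beta_cl = max(beta, lo)
        return ErrFit(beta_cl, (float(lo), np.inf), float(np.sum(w * ll)),
                      True, flags=["ci-upper unbounded"],
                      realization="combined", n_excluded=n_excluded,
                      per_realization=fits)
    hi = max(finite_uppers)
    span = hi - lo
    grid = np.linspace(lo - 0.5 * span, hi + 0.5 * span, 401)
    onehot = np.zeros((len(strata), len(stratum_ids)))
    onehot[np.arange(len(strata)), strata] = 1.0
    c_s = cases @ onehot
    mix = np.zeros_like(grid)
    for f, wv in zip(good, w):
        dose = rs.doses[int(f.realization), :, oi] * REALIZATION_DOSE_SCALE
        rr = 1.0 + grid[:, None] * dose[None, :]  # (grid, patients)
        valid = np.all(rr > 0, axis=1)
        prof = np.full(len(grid), -np.inf)
        if valid.any():
            lrr = np.log(rr[valid])
            t = (rr[valid] * py) @ onehot
            prof[valid] = lrr @ cases - np.log(t) @ c_s
        dens = np.exp(prof - prof.max())
        area = np.trapezoid(dens, grid)
        if area > 0:
            mix += wv * dens / area
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid)
                                           * 0.5 * (mix[1:] + mix[:-1]))])
    cdf /= cdf[-1]
    ci = (float(np.interp(0.025, cdf, grid)), float(np.interp(0.975, cdf, grid)))
    beta_cl = min(max(beta, ci[0]), ci[1])
    return ErrFit(beta_cl, ci, float(np.sum(w * ll)), True,
                  flags=[] if beta_cl == beta else ["estimate clipped to interval"],
                  realization="combined", n_excluded=n_excluded,
                  per_realization=fits)
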