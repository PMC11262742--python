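"""Low-positivity screen: Poisson regression with crossed random intercepts.

The daily number of positive tests per centre is modelled as

    n_positive[i] ~ Poisson(mu[i])
    log mu[i] = log n_tests[i] + beta0 + beta_cat[category(i)] + u[j(i)] + v[k(i)]

with the log of the daily test count as offset (so the linear predictor
describes the positivity *rate*), a fixed effect for the centre category,
and independent random intercepts for the centre, u_j ~ N(0, sigma_u^2), and
the calendar week, v_k ~ N(0, sigma_v^2). The week effects absorb changes in
background incidence; a centre's intercept u_j is its deviation from the
category mean positivity on the log scale.

Fraud interest is one-sided: a positive result imposed obligations on the
person tested, so fabricated results are disproportionately negative and a
*significantly low* u_j is the fraud signal. A centre is flagged when the
empirical-Bayes z statistic u_hat/se(u_hat) falls below the lower-alpha
normal quantile.

Estimation maximises the Laplace approximation to the marginal likelihood
(the random effects are integrated out around their joint conditional mode;
fixed effects are profiled in the inner penalised Newton solve). Adaptive
quadrature is not available for crossed designs; the Laplace approximation
is the standard choice there and is accurate once centres accumulate more
than a handful of expected positives.

Rows with ``n_tests == 0`` are dropped: the offset is undefined and a
zero-test day carries no positivity information.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
from scipy.stats import norm

from . import flags as fl
from .claims import StudyWindow

log = logging.getLogger(__name__)

#: Reference level for the category fixed effect.
REFERENCE_CATEGORY = "practice"

_SIGMA_FLOOR = 1e-6
_ETA_CAP = 30.0


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimisation fails.

    Carries the iteration trace in ``trace``.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class PositivityModel:
    """Crossed random-intercept Poisson model of daily positivity.

    Parameters
    ----------
    endog : array of daily positive counts
    exposure : array of daily test counts (>= 1)
    centre : array of centre labels (grouping factor j)
    week : array of 1-based calendar-week indices (grouping factor k)
    category : array of category labels per row (fixed effect)
    """

    def __init__(self, endog, exposure, centre, week, category):
        self.endog = np.asarray(endog, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        if (exposure < 1).any():
            raise ValueError("exposure (daily tests) must be >= 1 for every model row")
        if (self.endog < 0).any() or (self.endog > exposure).any():
            raise ValueError("positives must satisfy 0 <= n_positive <= n_tests")
        self.offset = np.log(exposure)
        self.n = len(self.endog)

        self.centre_labels, self._jc = np.unique(np.asarray(centre), return_inverse=True)
        self.week_labels, self._kc = np.unique(np.asarray(week), return_inverse=True)
        self.n_centres = len(self.centre_labels)
        self.n_weeks = len(self.week_labels)
        if self.n_centres < 2 or self.n_weeks < 2:
            raise ValueError("need at least 2 centres and 2 weeks with data")

        cats = pd.Series(np.asarray(category, dtype=object))
        levels = sorted(cats.unique())
        if REFERENCE_CATEGORY in levels:
            levels = [REFERENCE_CATEGORY] + [c for c in levels if c != REFERENCE_CATEGORY]
        self.category_levels = levels
        cols = [np.ones(self.n)]
        names = ["intercept"]
        for lev in levels[1:]:
            cols.append((cats == lev).to_numpy(dtype=float))
            names.append(f"category[{lev}]")
        self.exog = np.column_stack(cols)
        self.exog_names = names

        # per-centre category (constant within centre) for reporting
        first_row = pd.Series(np.arange(self.n)).groupby(self._jc).first().to_numpy()
        self.centre_category = cats.to_numpy()[first_row]

        self._Z = sp.hstack(
            [
                sp.csr_matrix(
                    (np.ones(self.n), (np.arange(self.n), self._jc)), shape=(self.n, self.n_centres)
                ),
                sp.csr_matrix(
                    (np.ones(self.n), (np.arange(self.n), self._kc)), shape=(self.n, self.n_weeks)
                ),
            ]
        ).tocsr()
        self._A = sp.hstack([sp.csr_matrix(self.exog), self._Z]).tocsr()

    # ------------------------------------------------------------------ #

    @classmethod
    def from_claims(cls, claims: pd.DataFrame, window: StudyWindow) -> "PositivityModel":
        """Build the model from a validated claims table, dropping zero-test days."""
        use = claims[claims["n_tests"] >= 1]
        if len(use) == 0:
            raise ValueError("no centre-days with invoiced tests")
        weeks = window.week_index(use["date"])
        return cls(
            endog=use["n_positive"].to_numpy(),
            exposure=use["n_tests"].to_numpy(),
            centre=use["centre_id"].to_numpy(),
            week=weeks,
            category=use["category"].to_numpy(),
        )

    # ------------------------------------------------------------------ #

    def _penalised_mode(self, sigma_u, sigma_v, delta0=None, maxiter=100, tol=1e-9):
        """Joint conditional mode of (beta, u, v) by damped Newton.

        Returns (delta, h, S_logdet, H) where h is the joint log density
        (Poisson log-likelihood without the log y! constant, plus the
        Gaussian log prior of the random effects including normalising
        constants) and S_logdet the log-determinant of the random-effect
        block of the negative Hessian at the mode.
        """
        p = self.exog.shape[1]
        J, K = self.n_centres, self.n_weeks
        q = J + K
        pen = np.concatenate(
            [np.zeros(p), np.full(J, 1.0 / sigma_u**2), np.full(K, 1.0 / sigma_v**2)]
        )
        const = -0.5 * J * np.log(2 * np.pi * sigma_u**2) - 0.5 * K * np.log(2 * np.pi * sigma_v**2)

        delta = np.zeros(p + q) if delta0 is None else delta0.copy()
        y = self.endog

        def objective(d):
            eta = np.clip(self.offset + self._A @ d, -_ETA_CAP, _ETA_CAP)
            mu = np.exp(eta)
            return (y * eta - mu).sum() - 0.5 * (pen * d * d).sum() + const, mu

        h, mu = objective(delta)
        for _ in range(maxiter):
            grad = self._A.T @ (y - mu) - pen * delta
            H = (self._A.T @ sp.diags(mu) @ self._A).toarray()
            H[np.diag_indices_from(H)] += pen
            try:
                cf = sla.cho_factor(H, lower=True)
            except sla.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                cf = sla.cho_factor(H, lower=True)
            step = sla.cho_solve(cf, grad)
            # damped update
            t = 1.0
            for _ in range(30):
                cand = delta + t * step
                h_new, mu_new = objective(cand)
                if h_new >= h - 1e-12:
                    break
                t /= 2
            delta, h, mu = cand, h_new, mu_new
            if np.max(np.abs(t * step)) < tol:
                break
        else:
            raise ConvergenceError(
                f"inner Newton did not converge (sigma_u={sigma_u:.4g}, sigma_v={sigma_v:.4g})"
            )

        S = (self._Z.T @ sp.diags(mu) @ self._Z).toarray()
        S[np.diag_indices_from(S)] += pen[p:]
        sgn, S_logdet = np.linalg.slogdet(S)
        return delta, h, S_logdet, H

    def _laplace_loglike(self, sigma_u, sigma_v, delta0=None):
        delta, h, S_logdet, _ = self._penalised_mode(sigma_u, sigma_v, delta0)
        q = self.n_centres + self.n_weeks
        return h + 0.5 * q * np.log(2 * np.pi) - 0.5 * S_logdet, delta

    # ------------------------------------------------------------------ #

    def fit(
        self,
        start_sigma=(0.5, 0.5),
        fix_sigma_u: float | None = None,
        fix_sigma_v: float | None = None,
        maxiter: int = 200,
        xtol: float = 1e-5,
    ) -> "PositivityResults":
        """Maximise the Laplace-approximate marginal likelihood.

        ``fix_sigma_u`` / ``fix_sigma_v`` pin a variance component (0 is
        allowed and removes the shrinkage limit: the effects are then driven
        to zero). The two free log-standard-deviations are optimised by
        Nelder-Mead with the inner penalised Newton warm-started between
        evaluations.
        """
        free = []
        if fix_sigma_u is None:
            free.append("u")
        if fix_sigma_v is None:
            free.append("v")

        state = {"delta": None}
        trace: list[tuple[float, float, float]] = []

        def sigmas(x):
            it = iter(x)
            su = np.exp(next(it)) if "u" in free else max(fix_sigma_u, _SIGMA_FLOOR)
            sv = np.exp(next(it)) if "v" in free else max(fix_sigma_v, _SIGMA_FLOOR)
            return float(su), float(sv)

        def negll(x):
            su, sv = sigmas(x)
            ll, delta = self._laplace_loglike(su, sv, state["delta"])
            state["delta"] = delta
            trace.append((su, sv, ll))
            return -ll

        if free:
            x0 = np.log(np.asarray(start_sigma[: len(free)], dtype=float))
            res = scipy.optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={"xatol": xtol, "fatol": 1e-7, "maxiter": maxiter * len(free)},
            )
            if not res.success and res.status != 1:  # status 1 = maxiter
                raise ConvergenceError(f"outer optimisation failed: {res.message}", trace)
            converged = bool(res.success)
            sigma_u, sigma_v = sigmas(res.x)
            llf = -res.fun
        else:
            sigma_u, sigma_v = sigmas(())
            llf, _ = self._laplace_loglike(sigma_u, sigma_v, state["delta"])
            converged = True

        for name, val, fixed in (("sigma_u", sigma_u, fix_sigma_u), ("sigma_v", sigma_v, fix_sigma_v)):
            if fixed is None and val < 1e-3:
                warnings.warn(f"{name} estimated at the boundary (~0); returning fit anyway")

        delta, h, S_logdet, H = self._penalised_mode(sigma_u, sigma_v, state["delta"])
        p = self.exog.shape[1]
        J = self.n_centres
        Hinv = sla.cho_solve(sla.cho_factor(H, lower=True), np.eye(H.shape[0]))
        cond_sd = np.sqrt(np.diag(Hinv))

        return PositivityResults(
            model=self,
            params=pd.Series(delta[:p], index=self.exog_names),
            bse=pd.Series(cond_sd[:p], index=self.exog_names),
            sigma_u=sigma_u,
            sigma_v=sigma_v,
            ranef_centre=pd.DataFrame(
                {
                    "category": self.centre_category,
                    "mode": delta[p : p + J],
                    "se": cond_sd[p : p + J],
                },
                index=pd.Index(self.centre_labels, name="centre_id"),
            ),
            ranef_week=pd.Series(delta[p + J :], index=pd.Index(self.week_labels, name="week")),
            llf=float(llf),
            converged=converged,
            n_rows=self.n,
            trace=trace,
        )


@dataclasses.dataclass
class PositivityResults:
    """Fit of the crossed random-intercept positivity model."""

    model: PositivityModel
    params: pd.Series
    bse: pd.Series
    sigma_u: float
    sigma_v: float
    ranef_centre: pd.DataFrame
    ranef_week: pd.Series
    llf: float
    converged: bool
    n_rows: int
    trace: list = dataclasses.field(default_factory=list, repr=False)

    @property
    def centre_z(self) -> pd.Series:
        """Empirical-Bayes z statistic u_hat / se(u_hat) per centre."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.ranef_centre["mode"] / self.ranef_centre["se"]
        return z

    def summary(self) -> str:
        lines = [
            "Poisson positivity model (crossed random intercepts, Laplace)",
            "=" * 62,
            f"rows: {self.n_rows}   centres: {self.model.n_centres}   weeks: {self.model.n_weeks}",
            f"log-likelihood (Laplace): {self.llf:.3f}   converged: {self.converged}",
            "",
            f"{'fixed effect':<22}{'estimate':>12}{'cond. se':>12}",
            "-" * 46,
        ]
        for name in self.params.index:
            lines.append(f"{name:<22}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        lines += [
            "-" * 46,
            f"sd(centre intercept) sigma_u: {self.sigma_u:.4f}",
            f"sd(week intercept)   sigma_v: {self.sigma_v:.4f}",
        ]
        return "\n".join(lines)

    def report(self) -> dict:
        """JSON-serialisable model report."""
        return {
            "fixed_effects": {k: float(v) for k, v in self.params.items()},
            "fixed_effects_se": {k: float(v) for k, v in self.bse.items()},
            "sigma_u": float(self.sigma_u),
            "sigma_v": float(self.sigma_v),
            "loglike_laplace": float(self.llf),
            "converged": bool(self.converged),
            "n_rows": int(self.n_rows),
            "n_centres": int(self.model.n_centres),
            "n_weeks": int(self.model.n_weeks),
        }

    def flag(self, alpha: float = 0.05, centres: pd.Index | None = None) -> pd.DataFrame:
        return flag_low_positivity(self, alpha=alpha, centres=centres)


def flag_low_positivity(
    fit: PositivityResults, alpha: float = 0.05, centres: pd.Index | None = None
) -> pd.DataFrame:
    """Flag centres whose empirical-Bayes intercept is significantly low.

    One-sided test: flagged iff u_hat/se < Phi^{-1}(alpha). ``centres`` may
    supply the full centre index (including centres with no model rows, which
    are ineligible); default is the centres in the fit.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = fit.centre_z
    se = fit.ranef_centre["se"]
    if (se <= 0).any():
        log.warning("centres with zero conditional sd marked ineligible")
    idx = pd.Index(sorted(centres), name="centre_id") if centres is not None else z.index
    eligible = pd.Series(idx.isin(z.index), index=idx) & (se.reindex(idx) > 0).fillna(False)
    score = z.reindex(idx)
    crit = norm.ppf(alpha)
    flagged = eligible & (score < crit)
    return fl.make_flag_table(idx, fl.LOW_POSITIVITY, eligible, score.where(eligible), flagged)
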