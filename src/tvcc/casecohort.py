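"""Case-cohort analysis of a standard case-control sample.

When cases are rare, the controls of a standard case-control study are
approximately representative of the population at risk and can be treated as
the *subcohort* of a case-cohort study.  Under the hazard model

    h(t | x, z) = h_0(t) exp(beta(t) x + gamma' z)

the exposure log hazard ratio ``beta(t)`` (a constant, a step function on a
period grid, a linear function of time, or any user-supplied basis) and the
time-constant covariate effects ``gamma`` are estimated by maximising the
pseudo-partial likelihood: each case is compared, at its event time, with
the controls still at risk then (same stratum if the design was frequency
matched, which corresponds to stratum-specific baseline hazards).

Because a case-control sample's controls are event-free by construction,
cases are never subcohort members: each case enters only its own risk set.
This is the structural equivalent of setting a case's entry time "just an
instant before" its event when using off-the-shelf Cox software — no
floating-point offset is ever added, so tied times stay exact.  Tied event
times are handled in Breslow's manner: one risk set per case with identical
membership rules.  The likelihood is "pseudo" because reusing the same
controls across risk sets induces dependence; a grouped sandwich variance
(clusters = subjects) is reported alongside the model-based one.

Time-varying exposures are supported through ``exposure_time``: a subject's
exposure status at time t is the right-continuous step 1{exposure_time <= t},
and with ``time_axis="u"`` the coefficient is modelled on the
time-since-exposure scale, each risk-set member contributing at its own
u = t_j - exposure_time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import covariate_columns, validate_subjects
from .errors import (
    ConfigurationError,
    PeriodAssignmentError,
    SeparationError,
)
from .optimize import invert_information, newton_maximize
from .periods import PeriodGrid
from .results import FitResult

__all__ = [
    "CoefficientModel",
    "ConstantCoefficient",
    "StepCoefficient",
    "LinearCoefficient",
    "CustomBasisCoefficient",
    "evaluate_beta",
    "RiskSet",
    "build_risk_sets",
    "CaseCohort",
    "CaseCohortResults",
]

logger = logging.getLogger(__name__)


class CoefficientModel:
    """Base class for the time-varying exposure coefficient beta(.)."""

    #: parameter names (without the exposure prefix)
    names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.names)

    def basis(self, times: np.ndarray) -> np.ndarray:
        """Basis matrix, shape (len(times), n_params): beta(t) = basis(t) @ coef."""
        raise NotImplementedError

    def beta_at(self, times, coef) -> np.ndarray:
        return self.basis(np.atleast_1d(np.asarray(times, float))) @ np.asarray(coef, float)


class ConstantCoefficient(CoefficientModel):
    """Time-constant log hazard ratio (the standard Cox model)."""

    names = ("",)

    def basis(self, times):
        return np.ones((len(times), 1))


class StepCoefficient(CoefficientModel):
    """Step-function beta(t) = sum_l v_l beta_l on a period grid.

    ``v_l`` indicates that t lies in period l; every evaluation time must
    fall inside the grid.
    """

    def __init__(self, grid: PeriodGrid):
        self.grid = grid
        self.names = tuple(grid.labels)

    def basis(self, times):
        idx = self.grid.assign(np.asarray(times, float))
        out = np.zeros((len(times), self.grid.n_periods))
        out[np.arange(len(times)), idx] = 1.0
        return out


class LinearCoefficient(CoefficientModel):
    """Linear trend beta(t) = beta_0 + beta_1 t."""

    names = ("b0", "b1")

    def basis(self, times):
        t = np.asarray(times, float)
        return np.column_stack([np.ones_like(t), t])


class CustomBasisCoefficient(CoefficientModel):
    """beta(t) expanded in user-supplied basis functions of time
    (the extension hook for splines and other smooth forms)."""

    def __init__(self, functions, names=None):
        self.functions = tuple(functions)
        self.names = tuple(names or (f"b{i}" for i in range(len(self.functions))))
        if len(self.names) != len(self.functions):
            raise ConfigurationError("one name per basis function required")

    def basis(self, times):
        t = np.asarray(times, float)
        cols = [np.broadcast_to(np.asarray(f(t), float), t.shape) for f in self.functions]
        out = np.column_stack(cols)
        if not np.all(np.isfinite(out)):
            raise ConfigurationError("basis functions must be finite at every event time")
        return out


def evaluate_beta(model: CoefficientModel, time, coef):
    """Log hazard ratio of the coefficient model at the given time(s)."""
    out = model.beta_at(time, coef)
    return float(out[0]) if np.ndim(time) == 0 else out


@dataclass
class RiskSet:
    """One case event time with its at-risk comparison set.

    ``member_rows`` are positional row indices into the subject table and
    always include ``case_row``.  A control is a member iff
    T_E < t_j <= T_I (at risk at its own index time included).
    """

    time: float
    case_row: int
    stratum: object
    member_rows: np.ndarray


def build_risk_sets(subjects: pd.DataFrame, stratified: bool = False,
                    include_case_followup: bool = False) -> list[RiskSet]:
    """One risk set per case, ordered by event time (Breslow ties: tied
    events give distinct risk sets with identical membership rules).

    With ``include_case_followup`` case rows are also at risk over
    (T_E, T_I] for *other* events — the situation of a subcohort containing
    the cases, e.g. when the "controls" are the entire remaining cohort.  In
    a genuine case-control sample this is off: controls are event-free, so
    cases appear only in their own risk set.
    """
    subjects = validate_subjects(subjects)
    t_e = subjects["entry_time"].to_numpy()
    t_i = subjects["index_time"].to_numpy()
    is_case = subjects["is_case"].to_numpy().astype(bool)
    strat = subjects["stratum"].to_numpy()
    case_rows = np.flatnonzero(is_case)
    if case_rows.size == 0:
        raise ConfigurationError("no cases: cannot build risk sets")
    order = case_rows[np.argsort(t_i[case_rows], kind="stable")]
    at_risk_pool = ~is_case if not include_case_followup else np.ones_like(is_case)
    sets: list[RiskSet] = []
    n_singleton = 0
    for row in order:
        tj = t_i[row]
        mask = at_risk_pool & (t_e < tj) & (tj <= t_i)
        if stratified:
            mask &= strat == strat[row]
        mask[row] = True  # the case belongs to its own risk set
        members = np.flatnonzero(mask)
        if members.size == 1:
            n_singleton += 1
        sets.append(RiskSet(float(tj), int(row), strat[row], members))
    if n_singleton:
        logger.warning(
            "%d of %d risk sets contain only the case and contribute no "
            "information about beta", n_singleton, len(sets),
        )
    return sets


class CaseCohort:
    """Case-cohort model for a case-control subject table.

    Parameters
    ----------
    subjects
        Subject table in the canonical schema; controls form the subcohort.
    coefficient
        :class:`CoefficientModel` for the exposure effect (default
        :class:`ConstantCoefficient`).
    stratified
        Stratum-specific baseline hazards (risk sets restricted to the
        case's frequency-matching stratum).
    time_axis
        ``"t"`` (event-time scale) or ``"u"`` (time since exposure; each
        member contributes at its own u = t_j - exposure_time).  Default:
        ``"u"`` when exposure times vary among exposed subjects, else
        ``"t"`` (the two coincide when everyone is exposed at time 0).
    robust
        Compute the grouped sandwich variance (clusters = subjects).
    include_case_followup
        Let case rows be at risk for other events over (T_E, T_I]; see
        :func:`build_risk_sets`.
    """

    def __init__(self, subjects: pd.DataFrame, coefficient: CoefficientModel | None = None,
                 stratified: bool = False, time_axis: str | None = None,
                 robust: bool = True, include_case_followup: bool = False):
        self.subjects = validate_subjects(subjects)
        self.coefficient = coefficient or ConstantCoefficient()
        self.stratified = bool(stratified)
        self.robust = bool(robust)
        self.risk_sets = build_risk_sets(self.subjects, stratified, include_case_followup)

        exp_times = self.subjects.loc[self.subjects["exposure"] != 0, "exposure_time"]
        if time_axis is None:
            time_axis = "u" if exp_times.nunique() > 1 else "t"
        if time_axis not in ("t", "u"):
            raise ConfigurationError("time_axis must be 't' or 'u'")
        self.time_axis = time_axis
        self._build_arrays()

    # -- internal flattened representation ---------------------------------
    def _build_arrays(self):
        subj = self.subjects
        zcols = covariate_columns(subj)
        self.covariate_names = zcols
        Z = subj[zcols].to_numpy(dtype=float) if zcols else np.empty((len(subj), 0))
        exposure = subj["exposure"].to_numpy(dtype=float)
        exp_time = subj["exposure_time"].to_numpy(dtype=float)  # NaN = never

        sizes = np.array([rs.member_rows.size for rs in self.risk_sets])
        self._starts = np.concatenate([[0], np.cumsum(sizes[:-1])]).astype(np.intp)
        mem = np.concatenate([rs.member_rows for rs in self.risk_sets])
        tj = np.repeat([rs.time for rs in self.risk_sets], sizes)
        case_row = np.repeat([rs.case_row for rs in self.risk_sets], sizes)
        self._members = mem
        self._is_case_row = mem == case_row

        with np.errstate(invalid="ignore"):
            x_at_t = exposure[mem] * (exp_time[mem] <= tj)
        times = tj if self.time_axis == "t" else tj - exp_time[mem]
        pb = self.coefficient.n_params
        B = np.zeros((mem.size, pb))
        exposed = x_at_t != 0
        if exposed.any():
            try:
                B[exposed] = (self.coefficient.basis(times[exposed])
                              * x_at_t[exposed, None])
            except PeriodAssignmentError as exc:
                raise PeriodAssignmentError(
                    f"coefficient-model support does not cover all event "
                    f"times on the {self.time_axis!r} axis: {exc}"
                ) from exc
        self._design = np.hstack([B, Z[mem]])
        prefix = "x" if self.time_axis == "t" else "x(u)"
        self.param_names = [f"{prefix}:{n}" if n else prefix
                            for n in self.coefficient.names] + zcols
        self._beta_slice = slice(0, pb)

        for k in range(pb):
            if not np.any(B[:, k]):
                raise SeparationError(
                    f"no exposed risk-set member falls in the support of "
                    f"coefficient {self.param_names[k]!r}; it is inestimable"
                )

    # -- likelihood --------------------------------------------------------
    def objective(self, params) -> tuple[float, np.ndarray, np.ndarray]:
        """Log pseudo-partial likelihood with analytic score and Hessian.

        Overflow is guarded by subtracting each risk set's maximum linear
        predictor before exponentiation.
        """
        theta = np.asarray(params, dtype=float)
        Phi = self._design
        starts = self._starts
        eta = Phi @ theta
        m = np.maximum.reduceat(eta, starts)
        seg = np.repeat(np.arange(len(starts)),
                        np.diff(np.concatenate([starts, [len(eta)]])))
        e = np.exp(eta - m[seg])
        denom = np.add.reduceat(e, starts)
        pi = e / denom[seg]
        ll = float(eta[self._is_case_row].sum() - (m + np.log(denom)).sum())
        score = Phi[self._is_case_row].sum(axis=0) - Phi.T @ pi
        S = np.add.reduceat(Phi * pi[:, None], starts, axis=0)
        hess = -((Phi * pi[:, None]).T @ Phi - S.T @ S)
        return ll, score, hess

    def loglik(self, params) -> float:
        return self.objective(params)[0]

    def _sandwich(self, theta, bread):
        Phi = self._design
        eta = Phi @ theta
        m = np.maximum.reduceat(eta, self._starts)
        seg = np.repeat(np.arange(len(self._starts)),
                        np.diff(np.concatenate([self._starts, [len(eta)]])))
        e = np.exp(eta - m[seg])
        denom = np.add.reduceat(e, self._starts)
        pi = e / denom[seg]
        resid = self._is_case_row.astype(float) - pi
        # Lin-Wei score residuals: each member's influence is measured
        # against its risk set's weighted mean covariate phi_bar_j
        S = np.add.reduceat(Phi * pi[:, None], self._starts, axis=0)
        rows = (Phi - S[seg]) * resid[:, None]
        n = len(self.subjects)
        s = np.zeros((n, Phi.shape[1]))
        np.add.at(s, self._members, rows)
        contributing = np.unique(self._members)
        G = contributing.size
        meat = s.T @ s
        if G > 1:
            meat *= G / (G - 1)
        return bread @ meat @ bread, G

    def fit(self, start=None) -> "CaseCohortResults":
        """Newton maximisation of the pseudo-partial likelihood."""
        sizes = np.array([rs.member_rows.size for rs in self.risk_sets])
        if not np.any(sizes > 1):
            raise ConfigurationError(
                "every risk set is a singleton; the likelihood is flat"
            )
        p = self._design.shape[1]
        theta0 = np.zeros(p) if start is None else np.asarray(start, float)
        theta, llf, info = newton_maximize(self.objective, theta0)
        _, _, hess = self.objective(theta)
        cov_model = invert_information(-hess)
        cov_robust, G = (None, None)
        if self.robust:
            cov_robust, G = self._sandwich(theta, cov_model)
        audit = {
            "n_risk_sets": len(self.risk_sets),
            "n_singletons": int(np.sum(sizes == 1)),
            "min_size": int(sizes.min()),
            "median_size": float(np.median(sizes)),
            "max_size": int(sizes.max()),
        }
        return CaseCohortResults(
            pd.Series(theta, index=self.param_names), cov_model, cov_robust,
            llf=llf, converged=info.converged, n_iter=info.n_iter,
            grad_norm=info.grad_norm, nobs=int(self._members.size),
            n_clusters=G, coefficient=self.coefficient,
            beta_slice=self._beta_slice, risk_set_audit=audit,
        )


class CaseCohortResults(FitResult):
    """Results of a case-cohort pseudo-partial-likelihood fit."""

    def __init__(self, *args, coefficient=None, beta_slice=None,
                 risk_set_audit=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.coefficient = coefficient
        self._beta_slice = beta_slice
        #: risk-set audit (count, size distribution, singletons)
        self.risk_set_audit = risk_set_audit or {}

    @property
    def beta_params(self) -> pd.Series:
        """Exposure coefficient estimates (the beta(.) parameters)."""
        return self.params.iloc[self._beta_slice]

    @property
    def gamma_params(self) -> pd.Series:
        """Time-constant covariate effects."""
        return self.params.iloc[self._beta_slice.stop:]

    def beta_at(self, times, robust: bool = False) -> pd.DataFrame:
        """Estimated log hazard ratio beta(t) with delta-method SE."""
        t = np.atleast_1d(np.asarray(times, float))
        B = self.coefficient.basis(t)
        coef = self.beta_params.to_numpy()
        cov = (self.cov_robust if robust else self.cov_model).to_numpy()
        cov_b = cov[self._beta_slice, self._beta_slice]
        est = B @ coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", B, cov_b, B))
        return pd.DataFrame({"time": t, "log_hr": est, "se": se, "hr": np.exp(est)})

    def summary(self, title: str = "Case-cohort pseudo-partial likelihood"):
        return super().summary(title)
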