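"""Period-wise logistic regression with control reuse.

The model for being a case in period ``l`` is

    logit Pr(D_l = 1 | x, z) = delta_0l + delta_Xl x + delta_Zl' z

fitted jointly across periods by maximising the full likelihood over the
period-expanded records (each case one record, each control one record per
eligible period).  ``delta_Xl`` is the period-l exposure log odds ratio; the
exposure-by-period columns use absolute coding (no reference period) so each
estimate is directly interpretable.  Reusing one control in several periods
induces dependence between likelihood contributions, so a clustered sandwich
variance (clusters = subjects) is reported alongside the model-based one.

Frequency matching is handled through the intercept structure: per-period
intercepts, per-stratum intercepts, their additive combination (default for
frequency-matched data), or the full period-by-stratum interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import validate_subjects
from .errors import ConfigurationError, SeparationError, SingularInformationError
from .optimize import invert_information as _invert_information
from .optimize import newton_maximize
from .periods import PeriodGrid, expand_to_periods
from .results import FitResult

__all__ = [
    "LogisticSpec",
    "build_design",
    "fit_logistic",
    "sandwich_variance",
    "PeriodLogistic",
    "PeriodLogisticResults",
]

logger = logging.getLogger(__name__)

_INTERCEPT_STRUCTURES = ("period_only", "stratum_only", "additive", "full_interaction")


@dataclass(frozen=True)
class LogisticSpec:
    """Parameter-sharing structure of the period-wise logistic model.

    Parameters
    ----------
    share_covariate_effects
        Use one covariate effect vector across periods (delta_Zl = delta_Z).
    share_intercept
        One common intercept delta_0 instead of per-period intercepts
        (ignored when ``stratify_intercepts`` is set).
    stratify_intercepts
        Include frequency-matching stratum terms in the intercept, with the
        layout chosen by ``intercept_structure``.
    intercept_structure
        ``"additive"`` (period intercepts plus stratum offsets, reference
        stratum dropped; the default for frequency-matched data),
        ``"stratum_only"`` (one intercept per stratum, shared across
        periods) or ``"full_interaction"`` (one intercept per period-stratum
        cell, the delta_0ls parameterisation).  Only used when
        ``stratify_intercepts`` is true.
    robust_se
        Always report the clustered sandwich variance.  Regardless of this
        flag, the sandwich is computed whenever any control contributes more
        than one record while some parameter is shared across periods.
    """

    share_covariate_effects: bool = True
    share_intercept: bool = False
    stratify_intercepts: bool = False
    intercept_structure: str = "additive"
    robust_se: bool = True

    def __post_init__(self):
        if self.intercept_structure not in _INTERCEPT_STRUCTURES[1:] + ("period_only",):
            raise ConfigurationError(
                f"unknown intercept_structure {self.intercept_structure!r}"
            )
        if self.stratify_intercepts and self.intercept_structure == "period_only":
            raise ConfigurationError(
                "stratify_intercepts requires a stratum-aware intercept_structure"
            )


def _period_names(periods, grid: PeriodGrid | None):
    if grid is not None:
        return {l: grid.label(l) for l in periods}
    return {l: f"p{l}" for l in periods}


def build_design(records: pd.DataFrame, spec: LogisticSpec, grid: PeriodGrid | None = None):
    """Build the design matrix for the period-expanded logistic model.

    Returns ``(X, y, clusters, names, x_names)`` where ``y`` is the
    period-wise case indicator, ``clusters`` the subject ids (one control
    reused across periods forms a single cluster) and ``x_names`` the
    exposure-by-period column names in period order.

    Raises
    ------
    SeparationError
        If some period contains cases but no control records (or vice
        versa), or an exposure-by-period column is identically zero, or the
        design is rank deficient.
    """
    if records.empty:
        raise ConfigurationError("no records to fit")

    if spec.stratify_intercepts:
        structure = spec.intercept_structure
    elif spec.share_intercept:
        structure = "const"
    else:
        structure = "period_only"

    if structure == "full_interaction":
        # A period-stratum cell containing only cases (or only controls)
        # identifies its own delta_0ls intercept at +/-infinity and carries
        # no information about the exposure effect: drop the cell (the
        # profile-likelihood limit, as with concordant strata in
        # conditional analyses).
        both = records.groupby(["period", "stratum"])["D"].transform(
            lambda d: d.min() < d.max())
        if not both.all():
            logger.info(
                "dropping %d records in period-stratum cells without both "
                "cases and controls", int((~both).sum()))
            records = records.loc[both].reset_index(drop=True)

    periods = np.sort(records["period"].unique())
    pname = _period_names(periods, grid)
    y = records["D"].to_numpy(dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise SeparationError("records contain only cases or only controls")
    for l in periods:
        sub = y[records["period"].to_numpy() == l]
        if sub.max() == 0 or sub.min() == 1:
            kind = "control" if sub.max() == 0 else "case"
            raise SeparationError(
                f"period {pname[l]} contains only {kind} records; "
                "the period intercept and exposure effect are inestimable"
            )

    cols: list[np.ndarray] = []
    names: list[str] = []
    per = records["period"].to_numpy()
    strata = records["stratum"].to_numpy()
    stratum_levels = pd.unique(pd.Series(strata).sort_values())

    if structure == "const":
        cols.append(np.ones_like(y))
        names.append("intercept")
    elif structure == "period_only":
        for l in periods:
            cols.append((per == l).astype(float))
            names.append(f"intercept:{pname[l]}")
    elif structure == "stratum_only":
        for s in stratum_levels:
            cols.append((strata == s).astype(float))
            names.append(f"intercept:s={s}")
    elif structure == "additive":
        for l in periods:
            cols.append((per == l).astype(float))
            names.append(f"intercept:{pname[l]}")
        for s in stratum_levels[1:]:  # reference stratum dropped
            cols.append((strata == s).astype(float))
            names.append(f"stratum:s={s}")
    else:  # full_interaction: delta_0ls, one cell per observed combination
        for l in periods:
            in_l = per == l
            for s in stratum_levels:
                cell = in_l & (strata == s)
                if cell.any():
                    cols.append(cell.astype(float))
                    names.append(f"intercept:{pname[l]},s={s}")

    x = records["exposure"].to_numpy(dtype=float)
    x_names = []
    for l in periods:
        col = x * (per == l)
        if not np.any(col):
            raise SeparationError(
                f"no exposed records in period {pname[l]}; delta_X{pname[l]} is inestimable"
            )
        cols.append(col)
        name = f"x:{pname[l]}"
        names.append(name)
        x_names.append(name)

    zcols = [c for c in records.columns if c not in
             ("subject_id", "period", "D", "exposure", "stratum")]
    for zc in zcols:
        z = records[zc].to_numpy(dtype=float)
        if spec.share_covariate_effects:
            cols.append(z)
            names.append(str(zc))
        else:
            for l in periods:
                cols.append(z * (per == l))
                names.append(f"{zc}:{pname[l]}")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SeparationError(
            "design matrix is rank deficient; some parameter is not estimable "
            "(check for empty period-stratum cells or constant exposure)"
        )
    return X, y, records["subject_id"].to_numpy(), names, x_names


def _loglik_score_hess(X, y, theta):
    eta = X @ theta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    grad = X.T @ (y - p)
    w = p * (1.0 - p)
    hess = -(X * w[:, None]).T @ X
    return ll, grad, hess


def sandwich_variance(X, y, estimates, clusters, ddof_correction: bool = True):
    """Clustered sandwich variance of the logistic estimates.

    bread = inverse observed information; meat = sum over clusters of the
    outer product of the within-cluster summed score, with a G/(G-1)
    small-sample factor (G = number of clusters).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(estimates, dtype=float)
    p = expit(X @ theta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError("observed information is singular") from exc
    bread = 0.5 * (bread + bread.T)
    scores = X * (y - p)[:, None]
    codes, _ = pd.factorize(np.asarray(clusters))
    G = codes.max() + 1
    s = np.zeros((G, X.shape[1]))
    np.add.at(s, codes, scores)
    meat = s.T @ s
    if ddof_correction and G > 1:
        meat *= G / (G - 1)
    return bread @ meat @ bread


class PeriodLogisticResults(FitResult):
    """Results of a period-wise logistic fit."""

    def __init__(self, *args, grid=None, x_names=None, record_audit=None, **kwargs):
        super().__init__(*args, **kwargs)
        self.grid = grid
        self._x_names = list(x_names or [])
        #: expanded-record counts (cases, control records, dropped controls)
        self.record_audit = record_audit or {}

    @property
    def period_log_or(self) -> pd.Series:
        """Exposure log odds ratios delta_Xl, one per period."""
        return self.params[self._x_names]

    def period_se(self, robust: bool = False) -> pd.Series:
        se = self.robust_bse if robust else self.bse
        if se is None:
            raise ValueError("robust variance was not computed")
        return se[self._x_names]

    def summary(self, title: str = "Period-wise logistic regression"):
        return super().summary(title)


def fit_logistic(records: pd.DataFrame, spec: LogisticSpec | None = None,
                 grid: PeriodGrid | None = None) -> PeriodLogisticResults:
    """Maximise the full period-expanded logistic likelihood.

    Newton–Raphson with step-halving; convergence at ``max|score| < 1e-8``
    and relative log-likelihood change below 1e-10 (at most 100 iterations).
    """
    spec = spec or LogisticSpec()
    X, y, clusters, names, x_names = build_design(records, spec, grid)
    theta, llf, info = newton_maximize(lambda t: _loglik_score_hess(X, y, t),
                                       np.zeros(X.shape[1]))
    _, _, hess = _loglik_score_hess(X, y, theta)
    cov_model = _invert_information(-hess)

    n_subjects = pd.unique(clusters).size
    reused = len(y) > n_subjects
    shared = (spec.share_intercept or spec.share_covariate_effects
              or (spec.stratify_intercepts and spec.intercept_structure != "full_interaction"))
    cov_robust = None
    if spec.robust_se or (reused and shared):
        cov_robust = sandwich_variance(X, y, theta, clusters)

    audit = {
        "n_case_records": int(y.sum()),
        "n_control_records": int(len(y) - y.sum()),
        "n_subjects": int(n_subjects),
        "n_dropped_controls": int(records.attrs.get("n_dropped_controls", 0)),
    }
    return PeriodLogisticResults(
        pd.Series(theta, index=names), cov_model, cov_robust,
        llf=llf, converged=info.converged, n_iter=info.n_iter,
        grad_norm=info.grad_norm, nobs=len(y), n_clusters=n_subjects,
        grid=grid, x_names=x_names, record_audit=audit,
    )


class PeriodLogistic:
    """Period-wise logistic model for a case-control subject table.

    Parameters
    ----------
    subjects
        Subject table in the canonical schema (see :mod:`tvcc.data`).
    grid
        The :class:`~tvcc.periods.PeriodGrid` of analysis periods.
    definition
        Control-eligibility definition, one of ``"i".."iv"``.
    reuse
        Reuse controls across eligible periods (the proposed scheme).  With
        ``False`` each control is allocated to a single definition-(i)
        eligible period by seeded greedy balancing.
    spec
        :class:`LogisticSpec`; defaults to per-period intercepts, shared
        covariate effects, robust SEs.
    allocation_seed
        Seed of the non-reuse allocation.
    """

    def __init__(self, subjects: pd.DataFrame, grid: PeriodGrid, definition: str = "i",
                 reuse: bool = True, spec: LogisticSpec | None = None,
                 allocation_seed: int = 0):
        self.subjects = validate_subjects(subjects)
        self.grid = grid
        self.definition = definition
        self.reuse = reuse
        self.spec = spec or LogisticSpec()
        self.records = expand_to_periods(self.subjects, grid, definition, reuse,
                                         allocation_seed)

    @classmethod
    def from_records(cls, records: pd.DataFrame, grid: PeriodGrid,
                     spec: LogisticSpec | None = None) -> "PeriodLogistic":
        """Build a model directly from pre-expanded period records."""
        obj = cls.__new__(cls)
        obj.subjects = None
        obj.grid = grid
        obj.definition = None
        obj.reuse = None
        obj.spec = spec or LogisticSpec()
        obj.records = records
        return obj

    def fit(self) -> PeriodLogisticResults:
        return fit_logistic(self.records, self.spec, self.grid)
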