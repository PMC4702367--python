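"""Newton–Raphson maximisation shared by both likelihoods.

Both objectives (the period-logistic full likelihood and the case-cohort
pseudo-partial likelihood) are concave, so plain Newton steps with
step-halving converge quadratically.  Convergence requires both a small
score and a small relative change in the objective; the strict defaults make
test oracles exact rather than approximately reproducible.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import ConvergenceError, SeparationError, SingularInformationError

__all__ = ["newton_maximize", "NewtonInfo", "invert_information"]


def invert_information(info: np.ndarray, cond_limit: float = 1e8) -> np.ndarray:
    """Invert an observed information matrix, refusing flat likelihoods.

    An eigenvalue ratio beyond ``cond_limit`` signals an (almost) flat
    direction of the converged likelihood — quasi-complete separation or an
    inestimable parameter — which Newton's score tolerance alone cannot
    distinguish from an interior maximum.
    """
    info = np.asarray(info, dtype=float)
    w = np.linalg.eigvalsh(0.5 * (info + info.T))
    if w[0] <= 0 or w[-1] / w[0] > cond_limit:
        from .errors import SeparationError

        raise SeparationError(
            "observed information is singular or nearly so at the optimum; "
            "some parameter is on the boundary (quasi-complete separation) "
            "or not identified by the data"
        )
    inv = np.linalg.inv(info)
    return 0.5 * (inv + inv.T)

#: iterate-norm bound beyond which we declare the maximiser non-finite; on
#: the log odds-ratio / log hazard-ratio scale a coefficient this large only
#: arises under (quasi-)complete separation
_PARAM_BOUND = 15.0


class NewtonInfo:
    """Diagnostics of a Newton run: iterations, gradient norm, convergence."""

    def __init__(self, n_iter: int, grad_norm: float, converged: bool):
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.converged = converged

    def __repr__(self):  # pragma: no cover
        return (f"NewtonInfo(n_iter={self.n_iter}, grad_norm={self.grad_norm:.3g}, "
                f"converged={self.converged})")


def newton_maximize(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
    theta0: np.ndarray,
    tol_grad: float = 1e-8,
    tol_rel_obj: float = 1e-10,
    max_iter: int = 100,
    max_halvings: int = 30,
):
    """Maximise a concave objective by Newton's method with step-halving.

    Parameters
    ----------
    objective
        Callable returning ``(value, gradient, hessian)`` at a parameter
        vector.  The Hessian is that of the objective (negative definite at
        an interior maximum).
    theta0
        Starting point.

    Returns
    -------
    theta, value, info
        The maximiser, the objective there, and a :class:`NewtonInfo`.

    Raises
    ------
    SeparationError
        If the iterates run away (no finite maximiser).
    SingularInformationError
        If the Hessian is singular at an iterate.
    ConvergenceError
        If tolerances are not met within ``max_iter`` iterations; the error
        carries the last iterate and gradient norm.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    value, grad, hess = objective(theta)
    if not np.isfinite(value):
        raise ConvergenceError("objective not finite at the starting point")
    grad_norm = float(np.max(np.abs(grad)))
    for it in range(1, max_iter + 1):
        if grad_norm < tol_grad:
            if np.max(np.abs(theta)) > _PARAM_BOUND:
                raise SeparationError(
                    f"score converged but |theta|_inf > {_PARAM_BOUND:g}: the "
                    "likelihood is flat at the boundary (quasi-complete separation)"
                )
            return theta, value, NewtonInfo(it - 1, grad_norm, True)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                f"singular Hessian at iteration {it} (|score|={grad_norm:.3g})"
            ) from exc
        # step-halving: never accept a step that lowers the objective
        scale = 1.0
        for _ in range(max_halvings):
            cand = theta + scale * step
            cval, cgrad, chess = objective(cand)
            if np.isfinite(cval) and cval >= value - 1e-14 * max(1.0, abs(value)):
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                "step-halving failed to find an ascent step",
                params=theta, grad_norm=grad_norm, n_iter=it,
            )
        rel_change = abs(cval - value) / max(1.0, abs(cval))
        theta, value, grad, hess = cand, cval, cgrad, chess
        grad_norm = float(np.max(np.abs(grad)))
        if np.max(np.abs(theta)) > _PARAM_BOUND:
            raise SeparationError(
                f"parameter estimates diverged (|theta|_inf > {_PARAM_BOUND:g}); "
                "the likelihood has no finite maximiser (perfect separation)"
            )
        if grad_norm < tol_grad and rel_change < tol_rel_obj:
            return theta, value, NewtonInfo(it, grad_norm, True)
    if grad_norm < tol_grad and np.max(np.abs(theta)) <= _PARAM_BOUND:
        return theta, value, NewtonInfo(max_iter, grad_norm, True)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (|score|={grad_norm:.3g})",
        params=theta, grad_norm=grad_norm, n_iter=max_iter,
    )
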