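"""Results containers shared by both estimators."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularInformationError

__all__ = ["FitResult"]


def _check_cov(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, rtol=1e-6, atol=1e-8):
        raise SingularInformationError(f"{name} variance matrix is not symmetric")
    return 0.5 * (cov + cov.T)


class FitResult:
    """Point estimates with model-based and (optionally) robust variances.

    Attributes
    ----------
    params : pandas.Series
        Named estimates on the log odds-ratio / log hazard-ratio scale.
    cov_model : pandas.DataFrame
        Inverse observed information.
    cov_robust : pandas.DataFrame or None
        Clustered sandwich variance (clusters = subjects), when computed.
    llf : float
        Log-likelihood (or log pseudo-partial likelihood) at the optimum.
    converged, n_iter, grad_norm
        Newton diagnostics.
    """

    def __init__(self, params: pd.Series, cov_model, cov_robust=None, *,
                 llf: float, converged: bool, n_iter: int, grad_norm: float,
                 nobs: int, n_clusters: int | None = None, extra: dict | None = None):
        self.params = params
        names = params.index
        self.cov_model = pd.DataFrame(_check_cov(cov_model, "model"), index=names, columns=names)
        self.cov_robust = (
            None if cov_robust is None
            else pd.DataFrame(_check_cov(cov_robust, "robust"), index=names, columns=names)
        )
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.grad_norm = float(grad_norm)
        self.nobs = int(nobs)
        self.n_clusters = None if n_clusters is None else int(n_clusters)
        self.extra = extra or {}

    @property
    def bse(self) -> pd.Series:
        """Model-based standard errors (inverse observed information)."""
        return pd.Series(np.sqrt(np.diag(self.cov_model)), index=self.params.index)

    @property
    def robust_bse(self) -> pd.Series | None:
        """Clustered sandwich standard errors, if computed."""
        if self.cov_robust is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05, robust: bool = False) -> pd.DataFrame:
        """Normal-theory confidence intervals on the log scale."""
        se = self.robust_bse if robust else self.bse
        if se is None:
            raise ValueError("robust variance was not computed")
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - q * se, "upper": self.params + q * se}
        )

    def to_frame(self) -> pd.DataFrame:
        """Parameter table: estimate, exp(estimate), SEs and 95% CI."""
        out = pd.DataFrame({
            "estimate": self.params,
            "ratio": np.exp(self.params),
            "model_se": self.bse,
        })
        if self.cov_robust is not None:
            out["robust_se"] = self.robust_bse
        ci = self.conf_int()
        out["ci_lower"] = ci["lower"]
        out["ci_upper"] = ci["upper"]
        return out

    def summary(self, title: str = "Fit results") -> str:
        """Plain-text summary table."""
        table = self.to_frame()
        head = [
            title,
            "=" * len(title),
            f"n records: {self.nobs}"
            + (f"   n clusters (subjects): {self.n_clusters}" if self.n_clusters else ""),
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged} "
            f"({self.n_iter} iterations, |score| = {self.grad_norm:.2e})",
            "",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v:10.4f}"):
            body = table.to_string()
        return "\n".join(head) + "\n" + body

    def __repr__(self):  # pragma: no cover
        return f"<{type(self).__name__}: {len(self.params)} parameters, llf={self.llf:.3f}>"
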