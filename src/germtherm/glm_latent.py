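"""Stage-one binomial-logit regression of per-seed germination and
latent-scale residual extraction (GRAMMAR-style pretreatment).

The binary germination indicator is first regressed on the design
nuisances (batch, multiplication year, conservation length and its
interaction with temperature, mains included for coding invariance); the
residuals on the linear-predictor ("latent") scale — by default the
working residuals (y - mu) / (mu (1 - mu)) — become the adjusted
germination rate GRA, which the stage-two gBLUP mixed model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import build_design

log = logging.getLogger(__name__)

DEFAULT_TERMS = ("batch", "year", "conservation", "temperature", "conservation:temperature")
PROB_CLIP = 1e-8


class SeparationError(ValueError):
    """Raised when the binomial likelihood is unbounded (complete
    separation), naming the offending term."""


class PretreatmentModel:
    """Binomial-logit model of the 0/1 germination indicator."""

    def __init__(self, df: pd.DataFrame, response: str = "germinated",
                 terms=DEFAULT_TERMS):
        self.df = df.reset_index(drop=True)
        y = self.df[response].to_numpy(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        self.y = y
        self.response = response
        self.terms = tuple(terms)
        # subset-constant terms (e.g. temperature within one treatment)
        # are dropped by the design builder
        self.X, self.xnames, self.meta = build_design(self.df, self.terms)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "PretreatmentResults":
        """IRLS (via the standard GLM machinery) to |delta deviance| < tol."""
        if np.ptp(self.y) == 0.0:
            raise SeparationError(
                "intercept: response is constant, the logit MLE is unbounded"
            )
        glm = sm.GLM(self.y, self.X, family=sm.families.Binomial())
        res = glm.fit(maxiter=max_iter, tol=tol, scale=1.0)
        # the solver history is prefixed with initialization values that are
        # not IRLS iterates; keep the monotone IRLS sequence proper
        raw = [d for d in res.fit_history.get("deviance", [res.deviance])
               if np.isfinite(d)]
        deviance_trace = raw[1:] if len(raw) > 1 else raw
        params = pd.Series(res.params, index=self.xnames)
        big = params.abs().idxmax()
        if abs(params[big]) > 30.0:
            raise SeparationError(
                f"{big}: coefficient diverged ({params[big]:.1f}); "
                "complete or quasi-complete separation"
            )
        converged = bool(res.converged)
        if not converged:
            log.warning("stage-one GLM did not converge in %d iterations", max_iter)
        mu = np.asarray(res.fittedvalues, dtype=float)
        return PretreatmentResults(
            model=self,
            params=params,
            bse=pd.Series(res.bse, index=self.xnames),
            fitted=mu,
            deviance_trace=deviance_trace,
            converged=converged,
        )


@dataclass
class PretreatmentResults:
    """Fitted stage-one GLM with latent-residual extraction."""

    model: PretreatmentModel
    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    deviance_trace: list
    converged: bool
    meta: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return self.deviance_trace[-1]

    def latent_residuals(self, kind: str = "working") -> np.ndarray:
        """Per-seed residuals on the latent (linear-predictor) scale.

        ``working`` (default, the GRAMMAR-family convention):
        (y - mu) / (mu (1 - mu)); ``pearson``: (y - mu)/sqrt(mu(1-mu));
        ``deviance``: signed square-root deviance contributions.  Fitted
        probabilities are clipped to [1e-8, 1 - 1e-8] with a logged count.
        The chosen kind is recorded in ``meta``.
        """
        y = self.model.y
        mu = np.asarray(self.fitted, dtype=float)
        n_clip = int(((mu < PROB_CLIP) | (mu > 1.0 - PROB_CLIP)).sum())
        if n_clip:
            log.info("clipped %d fitted probabilities at the 1e-8 boundary", n_clip)
        mu = np.clip(mu, PROB_CLIP, 1.0 - PROB_CLIP)
        if kind == "working":
            resid = (y - mu) / (mu * (1.0 - mu))
        elif kind == "pearson":
            resid = (y - mu) / np.sqrt(mu * (1.0 - mu))
        elif kind == "deviance":
            with np.errstate(divide="ignore", invalid="ignore"):
                d = -2.0 * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu))
            resid = np.sign(y - mu) * np.sqrt(np.clip(d, 0.0, None))
        else:
            raise ValueError("kind must be working, pearson or deviance")
        self.meta["residual_type"] = kind
        self.meta["n_clipped"] = n_clip
        return resid

    def summary(self) -> str:
        lines = [
            "stage-one binomial-logit pretreatment",
            f"  n = {self.model.y.size}   deviance = {self.deviance:.4f}"
            f"   converged: {self.converged}",
            f"  {'term':<34}{'coef':>12}{'SE':>11}",
        ]
        for name in self.params.index:
            lines.append(f"  {name:<34}{self.params[name]:>12.5g}{self.bse[name]:>11.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.round(10).to_dict(),
            "bse": self.bse.round(10).to_dict(),
            "deviance": float(self.deviance),
            "converged": self.converged,
            "residual_type": self.meta.get("residual_type"),
        }


def attach_gra(df: pd.DataFrame, residual_type: str = "working",
               per_species: bool = True, terms=DEFAULT_TERMS):
    """Fit the stage-one GLM (per species by default) and append a ``gra``
    column of latent-scale residuals.  Returns ``(df_with_gra, fits)``."""
    out = df.copy()
    out["gra"] = np.nan
    fits = {}
    groups = out.groupby("species", observed=True) if per_species else [("all", out)]
    for sp, sub in groups:
        res = PretreatmentModel(sub, terms=terms).fit()
        out.loc[sub.index, "gra"] = res.latent_residuals(residual_type)
        fits[str(sp)] = res
    return out, fits
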