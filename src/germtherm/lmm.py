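"""EM-REML mixed models with a genomic random effect (gBLUP).

Fits y = X beta + Z g + e with g ~ N(0, sigma2_g G) and
e ~ N(0, sigma2_e I) by EM-REML on Henderson's mixed-model equations,
followed by a single average-information (AI) step that supplies standard
errors for the variance components.  Heritability is
sigma2_g / (sigma2_g + sigma2_e).

The class layout follows the statsmodels convention: a
:class:`GBLUPModel` is built from data, its :meth:`~GBLUPModel.fit`
returns a :class:`GBLUPResults` carrying estimates, uncertainties,
per-accession gBLUPs (including accessions without phenotype records,
predicted through G), the REML log-likelihood trace and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .relatedness import RelationshipSet
from .simulate import _bend_grm

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8

CATEGORICAL_TERMS = ("temperature", "type", "batch", "year", "country", "species")
CONTINUOUS_TERMS = ("conservation", "latitude")


class DesignError(ValueError):
    pass


def build_design(df: pd.DataFrame, terms, standardize=("conservation",)):
    """Build a fixed-effect design matrix with an intercept.

    ``terms`` is drawn from {temperature, type, batch, year, conservation,
    country, temperature:country, conservation:temperature}.  Categorical
    terms use treatment coding against the first sorted level;
    ``temperature:country`` expands to country main effects plus one
    warm-temperature slope per country; continuous covariates named in
    ``standardize`` are centred and scaled.  Constant columns (terms
    constant within a data subset) are dropped with a log message; aliased
    columns are removed afterwards by pivoted rank detection.

    Returns ``(X, names, meta)`` where ``meta`` records factor levels and
    dropped columns.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    meta = {"factor_levels": {}, "dropped_constant": [], "dropped_aliased": []}

    def categorical(term: str):
        levels = sorted(df[term].astype(str).unique())
        meta["factor_levels"][term] = levels
        for lev in levels[1:]:
            cols.append((df[term].astype(str) == lev).to_numpy(float))
            names.append(f"{term}[{lev}]")

    def continuous(term: str, col_name=None):
        x = df[term].to_numpy(float)
        if term in standardize:
            sd = x.std(ddof=0)
            x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        cols.append(x)
        names.append(col_name or term)
        return x

    for term in terms:
        if term == "intercept":
            continue
        if term in CATEGORICAL_TERMS:
            categorical(term)
        elif term in CONTINUOUS_TERMS or term == "conservation_days":
            src = "conservation_days" if term == "conservation" else term
            x = df[src].to_numpy(float)
            if term == "conservation" or src in standardize:
                sd = x.std(ddof=0)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            cols.append(x)
            names.append(term)
        elif term == "temperature:country":
            temps = sorted(df["temperature"].astype(str).unique())
            warm = (df["temperature"].astype(str) == temps[-1]).to_numpy(float)
            levels = sorted(df["country"].astype(str).unique())
            meta["factor_levels"]["country"] = levels
            for lev in levels[1:]:
                cols.append((df["country"].astype(str) == lev).to_numpy(float))
                names.append(f"country[{lev}]")
            for lev in levels:
                cols.append(warm * (df["country"].astype(str) == lev).to_numpy(float))
                names.append(f"temperature[{temps[-1]}]:country[{lev}]")
        elif term == "conservation:temperature":
            x = df["conservation_days"].to_numpy(float)
            sd = x.std(ddof=0)
            x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            temps = sorted(df["temperature"].astype(str).unique())
            if len(temps) > 1:
                warm = (df["temperature"].astype(str) == temps[-1]).to_numpy(float)
                cols.append(x * warm)
                names.append(f"conservation:temperature[{temps[-1]}]")
        else:
            raise DesignError(f"unknown design term: {term}")

    X = np.column_stack(cols)
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            meta["dropped_constant"].append(names[j])
            log.info("dropping constant design column %s", names[j])
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]

    # pivoted-QR rank detection for aliased columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = sorted(piv[rank:])
        for j in aliased:
            meta["dropped_aliased"].append(names[j])
            log.info("dropping aliased design column %s", names[j])
        keep = [j for j in range(X.shape[1]) if j not in set(aliased)]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names, meta


class GBLUPModel:
    """Mixed model y = X beta + Z g + e with genomic covariance sigma2_g G."""

    def __init__(self, y, X, accession_index, G, accession_ids=None, xnames=None,
                 factor_levels=None, design_meta=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        self.accession_index = np.asarray(accession_index, dtype=int)
        G = np.asarray(G, dtype=float)
        self.G = _bend_grm(G)
        self.q = G.shape[0]
        self.n = self.y.size
        self.p = self.X.shape[1]
        self.accession_ids = (
            list(accession_ids) if accession_ids is not None else list(range(self.q))
        )
        self.xnames = list(xnames) if xnames is not None else [f"x{j}" for j in range(self.p)]
        self.factor_levels = dict(factor_levels or {})
        self.design_meta = dict(design_meta or {})
        if self.X.shape[0] != self.n or self.accession_index.size != self.n:
            raise ValueError("y, X and accession_index must agree in length")
        if self.accession_index.min() < 0 or self.accession_index.max() >= self.q:
            raise ValueError("accession_index out of range of G")

        # sufficient statistics (Z never formed densely)
        idx = self.accession_index
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.counts = np.bincount(idx, minlength=self.q).astype(float)
        self.Zty = np.bincount(idx, weights=self.y, minlength=self.q)
        self.ZtX = np.zeros((self.q, self.p))
        for j in range(self.p):
            self.ZtX[:, j] = np.bincount(idx, weights=self.X[:, j], minlength=self.q)
        cho = linalg.cho_factor(self.G)
        self.Ginv = linalg.cho_solve(cho, np.eye(self.q))
        self.logdetG = 2.0 * float(np.log(np.diag(cho[0])).sum())

    @classmethod
    def from_dataframe(cls, df, response, terms, grm, id_col="accession"):
        """Build from a phenotype table and a relationship matrix.

        ``grm`` may be a :class:`RelationshipSet` or a plain (ids, matrix)
        pair.  Rows with a missing response are dropped.
        """
        if isinstance(grm, RelationshipSet):
            ids, G = grm.accession_ids, grm.G
        else:
            ids, G = grm
        df = df.loc[df[response].notna()].reset_index(drop=True)
        if df.empty:
            raise ValueError("no observations with a non-missing response")
        pos = {a: i for i, a in enumerate(ids)}
        unknown = set(df[id_col]) - set(pos)
        if unknown:
            raise ValueError(f"accessions absent from the GRM: {sorted(unknown)[:5]}")
        idx = df[id_col].map(pos).to_numpy()
        X, names, meta = build_design(df, terms)
        return cls(
            y=df[response].to_numpy(float), X=X, accession_index=idx, G=G,
            accession_ids=ids, xnames=names,
            factor_levels=meta["factor_levels"], design_meta=meta,
        )

    # ---- internals -----------------------------------------------------

    def _mme(self, sigma2_g: float, sigma2_e: float):
        """Assemble and solve the mixed-model equations; return solution,
        inverse coefficient matrix and the residual sum y'Py * sigma2_e."""
        k = sigma2_e / sigma2_g
        C = np.empty((self.p + self.q, self.p + self.q))
        C[: self.p, : self.p] = self.XtX
        C[: self.p, self.p:] = self.ZtX.T
        C[self.p:, : self.p] = self.ZtX
        C[self.p:, self.p:] = k * self.Ginv
        C[self.p:, self.p:][np.diag_indices(self.q)] += self.counts
        rhs = np.concatenate([self.Xty, self.Zty])
        Cinv = linalg.inv(C)
        sol = Cinv @ rhs
        e_ss = self.yty - float(sol @ rhs)
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            raise np.linalg.LinAlgError("MME coefficient matrix not positive definite")
        return sol, Cinv, e_ss, logdetC

    def _reml_loglik(self, sigma2_g, sigma2_e, e_ss, logdetC) -> float:
        n, p, q = self.n, self.p, self.q
        logdetCstar = logdetC - (p + q) * np.log(sigma2_e)
        minus2 = (
            n * np.log(sigma2_e)
            + q * np.log(sigma2_g)
            + self.logdetG
            + logdetCstar
            + e_ss / sigma2_e
            + (n - p) * np.log(2.0 * np.pi)
        )
        return -0.5 * minus2

    def _vinv(self, v, S_cho, sigma2_e):
        """V^{-1} v via Woodbury using S = Z'Z/se2 + Ginv/sg2."""
        Ztv = np.bincount(self.accession_index, weights=v, minlength=self.q)
        u = linalg.cho_solve(S_cho, Ztv / sigma2_e)
        return (v - u[self.accession_index]) / sigma2_e

    def _ai_matrix(self, sigma2_g, sigma2_e, beta, g):
        """One average-information step: the 2x2 information matrix for
        (sigma2_g, sigma2_e) at the current estimates."""
        S = np.diag(self.counts / sigma2_e) + self.Ginv / sigma2_g
        S_cho = linalg.cho_factor(S)
        e_hat = self.y - self.X @ beta - g[self.accession_index]
        f_g = g[self.accession_index] / sigma2_g        # (dV/dsg2) P y
        f_e = e_hat / sigma2_e                          # (dV/dse2) P y = P y

        VinvX = np.column_stack(
            [self._vinv(self.X[:, j], S_cho, sigma2_e) for j in range(self.p)]
        )
        XtVinvX = self.X.T @ VinvX
        XtVinvX_cho = linalg.cho_factor(XtVinvX)

        def P(v):
            Vv = self._vinv(v, S_cho, sigma2_e)
            return Vv - VinvX @ linalg.cho_solve(XtVinvX_cho, VinvX.T @ v)

        Pf_g, Pf_e = P(f_g), P(f_e)
        AI = 0.5 * np.array(
            [[f_g @ Pf_g, f_g @ Pf_e], [f_e @ Pf_g, f_e @ Pf_e]]
        )
        return AI

    # ---- fitting -------------------------------------------------------

    def fit(self, start=None, tol: float = 1e-6, max_iter: int = 500) -> "GBLUPResults":
        """EM-REML until |delta log-likelihood| < tol, then one AI step for
        variance-component standard errors."""
        var_y = float(np.var(self.y)) or 1.0
        sigma2_g, sigma2_e = start if start is not None else (0.5 * var_y, 0.5 * var_y)
        sigma2_g = max(sigma2_g, VARIANCE_FLOOR)
        sigma2_e = max(sigma2_e, VARIANCE_FLOOR)
        trace = []
        converged = False
        boundary = False
        sol = None
        for _ in range(max_iter):
            sol, Cinv, e_ss, logdetC = self._mme(sigma2_g, sigma2_e)
            ll = self._reml_loglik(sigma2_g, sigma2_e, max(e_ss, 1e-300), logdetC)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            beta, g = sol[: self.p], sol[self.p:]
            Cgg = Cinv[self.p:, self.p:]
            sigma2_g_new = (g @ self.Ginv @ g + sigma2_e * np.trace(self.Ginv @ Cgg)) / self.q
            sigma2_e_new = max(e_ss, 0.0) / (self.n - self.p)
            sigma2_g = max(sigma2_g_new, VARIANCE_FLOOR)
            sigma2_e = max(sigma2_e_new, VARIANCE_FLOOR)
            if sigma2_g <= VARIANCE_FLOOR or sigma2_e <= VARIANCE_FLOOR:
                boundary = True
        if not converged:
            log.warning("EM-REML did not converge in %d iterations", max_iter)
        sol, Cinv, e_ss, logdetC = self._mme(sigma2_g, sigma2_e)
        beta, g = sol[: self.p], sol[self.p:]
        beta_cov = sigma2_e * Cinv[: self.p, : self.p]
        bse = np.sqrt(np.clip(np.diag(beta_cov), 0.0, None))

        vc_se = (np.nan, np.nan)
        if not boundary:
            try:
                AI = self._ai_matrix(sigma2_g, sigma2_e, beta, g)
                vc_cov = linalg.inv(AI)
                vc_se = tuple(np.sqrt(np.clip(np.diag(vc_cov), 0.0, None)))
            except np.linalg.LinAlgError:  # near-singular information
                log.warning("AI information matrix singular; no variance SEs")

        denom = sigma2_g + sigma2_e
        h2 = sigma2_g / denom if denom > 2 * VARIANCE_FLOOR else np.nan
        return GBLUPResults(
            model=self,
            params=pd.Series(beta, index=self.xnames),
            bse=pd.Series(bse, index=self.xnames),
            cov_params=pd.DataFrame(beta_cov, index=self.xnames, columns=self.xnames),
            sigma2_g=float(sigma2_g),
            sigma2_e=float(sigma2_e),
            sigma2_g_se=float(vc_se[0]),
            sigma2_e_se=float(vc_se[1]),
            gblups=pd.Series(g, index=self.accession_ids, name="gblup"),
            h2=float(h2) if np.isfinite(h2) else np.nan,
            loglik_trace=trace,
            converged=converged,
            boundary=boundary,
            n_obs=self.n,
            n_accessions=int((self.counts > 0).sum()),
        )


@dataclass
class GBLUPResults:
    """Converged EM-REML fit: estimates, uncertainties and diagnostics."""

    model: GBLUPModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma2_g: float
    sigma2_e: float
    sigma2_g_se: float
    sigma2_e_se: float
    gblups: pd.Series
    h2: float
    loglik_trace: list
    converged: bool
    boundary: bool
    n_obs: int
    n_accessions: int
    notes: list = field(default_factory=list)

    @property
    def llf(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.params)

    def wald_z(self, term: str):
        """Z-test of a fixed-effect coefficient: z = beta/SE, two-sided
        normal p-value."""
        if term not in self.params.index:
            raise KeyError(
                f"term {term!r} not in the fitted model (aliased or absent); "
                f"available: {list(self.params.index)}"
            )
        z = self.params[term] / self.bse[term]
        p = 2.0 * stats.norm.sf(abs(z))
        return float(z), float(p)

    def tukey_hsd(self, factor: str) -> pd.DataFrame:
        """Tukey HSD over the levels of a fitted factor.

        For each level pair, q = |difference| / (SE(difference)/sqrt(2))
        referred to the studentized-range distribution with residual
        degrees of freedom.
        """
        levels = self.model.factor_levels.get(factor)
        if levels is None:
            raise KeyError(f"{factor!r} is not a fitted factor")
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} has a single level")
        k = len(levels)
        names = list(self.params.index)

        def contrast(level):
            c = np.zeros(len(names))
            col = f"{factor}[{level}]"
            if col in names:
                c[names.index(col)] = 1.0
            return c

        rows = []
        V = self.cov_params.to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                c = contrast(levels[j]) - contrast(levels[i])
                diff = float(c @ self.params.to_numpy())
                se_diff = float(np.sqrt(c @ V @ c))
                if se_diff == 0.0:
                    q, p = np.nan, np.nan
                else:
                    q = abs(diff) / (se_diff / np.sqrt(2.0))
                    p = float(stats.studentized_range.sf(q, k, max(self.df_resid, 2)))
                rows.append((levels[i], levels[j], diff, se_diff, q, p))
        return pd.DataFrame(
            rows, columns=["level_1", "level_2", "difference", "se_diff", "q", "p"]
        )

    def summary(self) -> str:
        lines = [
            "gBLUP mixed model (EM-REML, AI standard errors)",
            f"  observations: {self.n_obs}   phenotyped accessions: {self.n_accessions}",
            f"  converged: {self.converged}   EM iterations: {len(self.loglik_trace)}"
            + ("   [variance at boundary]" if self.boundary else ""),
            f"  REML log-likelihood: {self.llf:.4f}",
            f"  sigma2_g = {self.sigma2_g:.6g} (SE {self.sigma2_g_se:.3g})",
            f"  sigma2_e = {self.sigma2_e:.6g} (SE {self.sigma2_e_se:.3g})",
            f"  heritability h2 = {self.h2:.4f}",
            "",
            f"  {'term':<34}{'coef':>12}{'SE':>11}{'z':>9}{'p':>11}",
        ]
        for name in self.params.index:
            b, s = self.params[name], self.bse[name]
            z = b / s if s > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"  {name:<34}{b:>12.5g}{s:>11.4g}{z:>9.3f}{p:>11.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.round(10).to_dict(),
            "bse": self.bse.round(10).to_dict(),
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "sigma2_g_se": self.sigma2_g_se,
            "sigma2_e_se": self.sigma2_e_se,
            "h2": self.h2,
            "loglik": self.llf,
            "n_iter": len(self.loglik_trace),
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_accessions": self.n_accessions,
            "notes": self.notes,
        }


# ---- functional surface ----------------------------------------------------


def fit_emreml(y, X, accession_index, G, tol=1e-6, max_iter=500, start=None,
               accession_ids=None, xnames=None) -> GBLUPResults:
    """Functional wrapper around :class:`GBLUPModel`."""
    model = GBLUPModel(y, X, accession_index, G, accession_ids=accession_ids,
                       xnames=xnames)
    return model.fit(start=start, tol=tol, max_iter=max_iter)


def extract_gblups(fit: GBLUPResults) -> pd.Series:
    """Per-accession genetic values, one per accession in G (accessions
    without phenotype rows are predicted through relationship)."""
    return fit.gblups


def heritability(fit: GBLUPResults) -> float:
    """sigma2_g / (sigma2_g + sigma2_e); NaN when both components sit at
    the lower bound."""
    return fit.h2


def wald_z_test(fit: GBLUPResults, term: str):
    return fit.wald_z(term)


def tukey_hsd(fit: GBLUPResults, factor: str) -> pd.DataFrame:
    return fit.tukey_hsd(factor)


GT_TERMS = ("temperature", "type", "batch", "year", "conservation")
GRA_TERMS = ("temperature", "type")


def _terms_for(trait: str, suite: str):
    base = GT_TERMS if trait == "GT" else GRA_TERMS
    if suite.endswith("d"):
        base = tuple(t for t in base if t != "temperature") + ("temperature:country",)
    return base


def fit_model_suite(df, grm, trait: str, suite: str, species=None,
                    response=None, tol=1e-6, max_iter=500) -> dict:
    """Fit a suite of gBLUP models on (subsets of) a phenotype table.

    ``suite``: "1"/"3" pooled; "1b"/"3b" split by type; "1c"/"3c" split by
    type x temperature; "3d" pooled with per-country temperature slopes.
    Trait "GT" fits germination time in hours on germinated seeds; trait
    "GRA" fits the latent-scale adjusted germination rate (requires a
    ``gra`` column from the stage-one GLM).  Within-subset constant terms
    (e.g. temperature in a "c" fit) are dropped automatically by the
    design builder.  Returns a dict keyed by subset label.
    """
    if trait not in ("GT", "GRA"):
        raise ValueError("trait must be GT or GRA")
    family = suite[0]
    if trait == "GRA" and family == "1":
        log.info("suite %s requested for trait GRA; treating as model family 3", suite)
        suite = "3" + suite[1:]
    if trait == "GT" and family == "3":
        log.info("suite %s requested for trait GT; treating as model family 1", suite)
        suite = "1" + suite[1:]
    if suite not in ("1", "1b", "1c", "3", "3b", "3c", "3d"):
        raise ValueError(f"unknown suite {suite!r}")

    data = df
    if species is not None:
        data = data.loc[data["species"] == species]
    if trait == "GT":
        data = data.loc[data["germinated"].astype(bool)]
        response = response or "gt_hours"
    else:
        response = response or "gra"
        if response not in data.columns:
            raise ValueError("GRA response column missing; run the stage-one GLM first")

    terms = _terms_for(trait, suite)

    def one(sub: pd.DataFrame, label: str):
        if sub.empty:
            log.info("subset %s empty; skipped", label)
            return None
        model = GBLUPModel.from_dataframe(sub, response, terms, grm)
        return model.fit(tol=tol, max_iter=max_iter)

    fits = {}
    if suite in ("1", "3", "3d"):
        res = one(data, "all")
        if res is not None:
            fits["all"] = res
    elif suite in ("1b", "3b"):
        for t, sub in data.groupby("type", observed=True):
            res = one(sub, str(t))
            if res is not None:
                fits[str(t)] = res
    else:  # 1c / 3c: type x temperature
        for (t, temp), sub in data.groupby(["type", "temperature"], observed=True):
            label = f"{t}:{temp}"
            res = one(sub, label)
            if res is not None:
                fits[label] = res
    return fits
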