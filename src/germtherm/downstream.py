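"""Downstream accession-level regressions.

Builds per-accession summaries (cold gBLUP C, warm gBLUP W, heat
tolerance H = W - C, latitude, emergence) and fits the three ordinary
least-squares models that close the analysis:

* cross-temperature comparison  W = mu4 + b C + e  (ranking stability);
* heat tolerance vs latitude    H = mu5 + b1 C + b2 l + e, per type,
  a Finlay-Wilkinson-like regression of G-by-E on an environmental proxy;
* emergence prediction          E = mu6 + mu3 + b C + e, with mu3 a fixed
  offset taken from the cold-temperature stage-two fit.

Coefficients are tested with Z-tests (normal reference) and model quality
is reported as adjusted R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


class DownstreamError(ValueError):
    pass


#: canonical column layout of an accession summary table
ACCESSION_SUMMARY_COLUMNS = [
    "accession", "species", "type", "country", "latitude", "C", "W", "H", "E",
]


@dataclass
class AccessionSummary:
    """One accession: gBLUPs at both temperatures and field covariates."""

    accession: str
    species: str
    type: str
    country: str | None = None
    latitude: float | None = None
    C: float | None = None
    W: float | None = None
    H: float | None = None
    E: float | None = None


@dataclass
class LinearFit:
    """An OLS fit with Z-tests and adjusted R^2."""

    params: pd.Series
    bse: pd.Series
    z: pd.Series
    p: pd.Series
    n: int
    r2: float
    adj_r2: float
    offset: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.n <= len(self.params):
            raise DownstreamError("more coefficients than observations")

    def summary(self) -> str:
        lines = [
            f"OLS {self.label}".rstrip(),
            f"  n = {self.n}   R2 = {self.r2:.4f}   adjusted R2 = {self.adj_r2:.4f}"
            + (f"   fixed offset = {self.offset:.6g}" if self.offset is not None else ""),
            f"  {'term':<16}{'coef':>12}{'SE':>11}{'z':>9}{'p':>11}",
        ]
        for t in self.params.index:
            lines.append(
                f"  {t:<16}{self.params[t]:>12.5g}{self.bse[t]:>11.4g}"
                f"{self.z[t]:>9.3f}{self.p[t]:>11.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "params": self.params.round(12).to_dict(),
            "bse": self.bse.round(12).to_dict(),
            "z": self.z.round(6).to_dict(),
            "p": self.p.to_dict(),
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "offset": self.offset,
        }


def adjusted_r2(r2: float, n: int, p_terms: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p_terms - 1)."""
    if n <= p_terms + 1:
        raise DownstreamError("adjusted R^2 undefined: n <= p_terms + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_terms - 1)


def _ols(y: np.ndarray, X: pd.DataFrame, label: str, offset: float | None = None) -> LinearFit:
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    params = pd.Series(res.params, index=res.model.exog_names)
    bse = pd.Series(res.bse, index=res.model.exog_names)
    z = params / bse
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)
    n = int(res.nobs)
    r2 = float(res.rsquared)
    return LinearFit(
        params=params.rename({"const": "intercept"}),
        bse=bse.rename({"const": "intercept"}),
        z=z.rename({"const": "intercept"}),
        p=p.rename({"const": "intercept"}),
        n=n,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, X.shape[1]),
        offset=offset,
        label=label,
    )


def heat_tolerance(summaries: pd.DataFrame) -> pd.DataFrame:
    """Append H = W - C; accessions missing either gBLUP are excluded with
    a log entry."""
    out = summaries.copy()
    missing = out["W"].isna() | out["C"].isna()
    if missing.any():
        log.info(
            "excluding %d accessions without both gBLUPs: %s",
            int(missing.sum()), list(out.loc[missing, "accession"].head()),
        )
        out = out.loc[~missing].reset_index(drop=True)
    out["H"] = out["W"] - out["C"]
    return out


def fit_cross_temperature(summaries: pd.DataFrame, trait: str = "") -> dict:
    """Model (4): OLS of the warm gBLUP on the cold gBLUP with intercept.

    Returns a dict of :class:`LinearFit`: ``"pooled"`` plus one fit per
    accession type with at least 3 accessions.
    """
    df = summaries.dropna(subset=["C", "W"])
    if len(df) < 3:
        raise DownstreamError("need at least 3 accessions")
    if np.ptp(df["C"].to_numpy()) == 0.0:
        raise DownstreamError("zero variance in the cold gBLUP")
    fits = {
        "pooled": _ols(df["W"].to_numpy(), df[["C"]], f"W ~ C {trait} pooled".strip())
    }
    for t, sub in df.groupby("type", observed=True):
        if len(sub) >= 3 and np.ptp(sub["C"].to_numpy()) > 0:
            fits[str(t)] = _ols(sub["W"].to_numpy(), sub[["C"]], f"W ~ C {trait} {t}".strip())
    return fits


def fit_latitude_model(summaries: pd.DataFrame, joint: bool = False) -> dict:
    """Model (5): OLS of heat tolerance H on the cold gBLUP (baseline
    control) and latitude, fitted separately for wild and landrace
    accessions; ``joint=True`` adds a pooled fit with a type dummy."""
    df = summaries.dropna(subset=["C", "H", "latitude"])
    fits = {}
    groups = list(df.groupby("type", observed=True))
    if joint:
        groups.append(("joint", df))
    for t, sub in groups:
        if len(sub) < 4:
            log.info("latitude model: subset %s has < 4 accessions; skipped", t)
            continue
        r = np.corrcoef(sub["C"], sub["latitude"])[0, 1]
        if abs(r) > 0.999:
            raise DownstreamError(
                f"cold gBLUP and latitude are collinear (r = {r:.4f}) in subset {t}"
            )
        X = sub[["C", "latitude"]].copy()
        if t == "joint" and sub["type"].nunique() > 1:
            X["type_wild"] = (sub["type"] == "wild").astype(float)
        fits[str(t)] = _ols(sub["H"].to_numpy(), X, f"H ~ C + latitude {t}")
    return fits


def fit_emergence_model(summaries: pd.DataFrame, mu3: float) -> LinearFit:
    """Model (6): OLS of the emergence rate on the cold gBLUP, with the
    stage-two cold intercept mu3 entered as a fixed offset (subtracted
    from E, never re-estimated)."""
    if mu3 is None or not np.isfinite(mu3):
        raise DownstreamError("mu3 (cold stage-two intercept) is required")
    df = summaries.dropna(subset=["C", "E"])
    if len(df) < 3:
        raise DownstreamError("need at least 3 accessions with emergence")
    if np.ptp(df["C"].to_numpy()) == 0.0:
        raise DownstreamError("zero variance in the cold gBLUP")
    y = df["E"].to_numpy(float) - mu3
    return _ols(y, df[["C"]], "E - mu3 ~ C", offset=float(mu3))


def build_accession_summaries(
    fits_cold: dict,
    fits_warm: dict,
    meta: pd.DataFrame,
    emergence: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-accession summary table.

    ``fits_cold``/``fits_warm`` map accession type to a stage-two fit;
    each accession's C and W come from the fit of its own type.  ``meta``
    needs columns accession, species, type, country, latitude.
    """
    rows = []
    for _, m in meta.drop_duplicates("accession").iterrows():
        t = str(m["type"])
        fc, fw = fits_cold.get(t), fits_warm.get(t)
        C = float(fc.gblups.get(m["accession"], np.nan)) if fc is not None else np.nan
        W = float(fw.gblups.get(m["accession"], np.nan)) if fw is not None else np.nan
        E = np.nan
        if emergence is not None and m["accession"] in emergence.index:
            E = float(emergence[m["accession"]])
        rows.append(
            (m["accession"], m.get("species"), t, m.get("country"),
             float(m["latitude"]) if pd.notna(m.get("latitude")) else np.nan,
             C, W, np.nan, E)
        )
    df = pd.DataFrame(rows, columns=ACCESSION_SUMMARY_COLUMNS)
    return heat_tolerance(df)
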