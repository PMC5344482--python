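"""Feed-efficiency trait derivation: FCR, metabolic body weight, RFI, y_c.

FCR is the ratio of average daily feed intake to average daily gain. RFI is
the residual of the feed-intake regression

    ADFI = mu + sex + hatch + b1 * MBW^0.75 + b2 * ADG + e,

where MBW is the mid-test body weight, so RFI is exactly orthogonal to body
size and gain over the fitting set by OLS construction. The corrected
phenotype y_c removes sex and hatch effects (OLS on the full data) while
retaining the trait mean; RFI is already corrected, so its y_c is itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TraitError(ValueError):
    pass


@dataclass
class RFIFit:
    """Coefficients and residuals of the feed-intake regression."""

    coef: pd.Series
    residuals: pd.Series = field(repr=False)
    rank: int = 0
    n: int = 0
    column_names: list[str] = field(default_factory=list)


def compute_fcr(adfi, adg) -> np.ndarray:
    """Elementwise feed conversion ratio ADFI / ADG.

    Records with ADG <= 0 are flagged (NaN) and logged, not raised: a bird
    that lost weight has no meaningful conversion ratio.
    """
    adfi = np.asarray(adfi, dtype=float)
    adg = np.asarray(adg, dtype=float)
    if adfi.shape != adg.shape:
        raise TraitError("ADFI and ADG must have matching shapes")
    invalid = ~(adg > 0)
    if invalid.any():
        logger.warning("compute_fcr: %d record(s) with ADG <= 0 flagged NaN",
                       int(invalid.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = adfi / adg
    out[invalid] = np.nan
    return out


def compute_mbw(bw_start, bw_end) -> np.ndarray:
    """Metabolic body weight: ((BW_start + BW_end) / 2) ** 0.75."""
    bw_start = np.asarray(bw_start, dtype=float)
    bw_end = np.asarray(bw_end, dtype=float)
    if np.any(bw_start <= 0) or np.any(bw_end <= 0):
        raise TraitError("body weights must be positive")
    return ((bw_start + bw_end) / 2.0) ** 0.75


def _design(df: pd.DataFrame, factors=(), covariates=()):
    """Intercept + treatment-coded dummies + centered covariates.

    Covariates are centered for conditioning only; residuals are unchanged
    and the reported intercept is mapped back to the uncentered scale.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        d = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(c)
    centers = {}
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        centers[c] = x.mean()
        cols.append(x - centers[c])
        names.append(c)
    return np.column_stack(cols), names, centers


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design: aliased columns resolved by "
                      "minimum-norm least squares", stacklevel=2)
    resid = y - X @ beta
    return pd.Series(beta, index=names), resid, rank


def compute_rfi(traits: pd.DataFrame):
    """Residual feed intake and the fit that produced it.

    Requires columns ADFI, ADG, sex, hatch and either MBW or
    BW_start/BW_end. Returns (rfi Series, RFIFit); mean(rfi) is zero to
    numerical tolerance and rfi is OLS-orthogonal to every model column.
    """
    df = traits.copy()
    for col in ("ADFI", "ADG", "sex", "hatch"):
        if col not in df.columns:
            raise TraitError(f"trait table lacks column {col!r}")
    if "MBW" not in df.columns:
        df["MBW"] = compute_mbw(df["BW_start"], df["BW_end"])
    for f in ("sex", "hatch"):
        if df[f].nunique() < 1:
            raise TraitError(f"factor {f!r} has no levels")
    X, names, centers = _design(df, factors=("sex", "hatch"),
                                covariates=("MBW", "ADG"))
    y = df["ADFI"].to_numpy(dtype=float)
    coef, resid, rank = _ols(X, y, names)
    # report the intercept on the uncentered covariate scale
    coef_out = coef.copy()
    coef_out["intercept"] = coef["intercept"] - sum(
        coef[c] * centers[c] for c in centers)
    rfi = pd.Series(resid, index=df.index, name="RFI")
    fit = RFIFit(coef=coef_out, residuals=rfi, rank=rank, n=len(df),
                 column_names=names)
    return rfi, fit


def derive_traits(traits: pd.DataFrame):
    """Add MBW, FCR and RFI columns to a post-QC trait table.

    Returns (augmented copy, RFIFit).
    """
    out = traits.copy()
    out["MBW"] = compute_mbw(out["BW_start"], out["BW_end"])
    out["FCR"] = compute_fcr(out["ADFI"], out["ADG"])
    rfi, fit = compute_rfi(out)
    out["RFI"] = rfi
    return out, fit


def corrected_phenotype(values: pd.Series, sex: pd.Series, hatch: pd.Series,
                        trait_name: str) -> pd.Series:
    """Phenotype corrected for sex and hatch, retaining the trait mean.

    For RFI the values are returned unchanged (already corrected by
    construction). For every other trait, y_c = OLS residual + grand mean
    from the regression of the trait on sex and hatch over the full data.
    """
    values = pd.Series(values).astype(float)
    if trait_name == "RFI":
        return values.copy()
    df = pd.DataFrame({"y": values, "sex": sex, "hatch": hatch})
    X, names, _ = _design(df, factors=("sex", "hatch"))
    _, resid, _ = _ols(X, df["y"].to_numpy(), names)
    return pd.Series(resid + values.mean(), index=values.index,
                     name=f"yc_{trait_name}")
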