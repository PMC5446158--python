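"""Linear mixed models for FP profiles and flowering volume.

The FP model has the full factorial of P, K(+u), N, growing-season
month (May-October) and ecoregion as fixed effects, with random
intercepts for site and for block nested within site; the volume model
drops the month factor. Fitting is REML (statsmodels MixedLM). F tests
are marginal (each term adjusted for all others) under sum-to-zero
factor coding, which on the balanced factorial coincides with the
sequential tests. Denominator df follow a containment-style rule: the
ecoregion main effect, a between-site comparison, is tested against the
site stratum (n_sites - n_ecoregions); every other term against the
residual stratum (n_obs - fixed-effect rank). Months are treated as
independent residuals within a plot — a deliberate match to the
original analysis and a known pseudo-replication caveat.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

GROWING_SEASON = tuple(range(5, 11))  # May..October

#: Display label and model column for each experimental factor, in the
#: canonical reporting order (nutrients, then month, then ecoregion).
FACTOR_LABELS = {
    "C(trt_P, Sum)": "P",
    "C(trt_K, Sum)": "K+μ",
    "C(trt_N, Sum)": "N",
    "C(month, Sum)": "Month",
    "C(ecoregion, Sum)": "Ecoregion",
}
_FACTOR_RANK = {label: i for i, label in enumerate(FACTOR_LABELS.values())}

FP_RHS = " * ".join(list(FACTOR_LABELS)[:5])
VOLUME_RHS = " * ".join(k for k in FACTOR_LABELS if "month" not in k)


class FitError(RuntimeError):
    """Model could not be fit (singular design, zero variance, no convergence)."""


@dataclass
class PhenoLMM:
    """Handle around a fitted mixed model plus design bookkeeping."""

    result: object           # statsmodels MixedLMResults
    design_info: object      # patsy DesignInfo of the fixed effects
    data: pd.DataFrame
    response: str
    n_obs: int
    rank: int
    n_sites: int
    n_ecoregions: int
    method: str = "REML"

    @property
    def ddf_residual(self) -> int:
        return self.n_obs - self.rank

    @property
    def ddf_site(self) -> int:
        return self.n_sites - self.n_ecoregions

    def fe_cov(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]


def _check_design(df: pd.DataFrame, response: str) -> None:
    if df.empty:
        raise FitError("no observations to fit")
    if float(df[response].var()) == 0.0:
        raise FitError(f"response {response!r} has zero variance; nothing to model")
    for col in ("month", "ecoregion", "trt_N", "trt_P", "trt_K"):
        if col in df.columns and df[col].nunique() < 2 and col in ("ecoregion", "month"):
            raise FitError(
                f"factor {col!r} has a single level; the factorial model is degenerate"
            )


def _fit_mixed(df: pd.DataFrame, formula: str, response: str) -> PhenoLMM:
    _check_design(df, response)
    df = df.copy()
    df["site_block"] = df["site"].astype(str) + "/" + df["block"].astype(str)
    model = smf.mixedlm(
        formula, df, groups=df["site"],
        re_formula="1", vc_formula={"block": "0 + C(site_block)"},
    )
    rank = int(np.linalg.matrix_rank(model.exog))
    k_fe = model.exog.shape[1]
    if rank < k_fe:
        raise FitError(
            f"singular fixed-effect design: rank {rank} < {k_fe} columns "
            "(incomplete factorial or aliased factors)"
        )
    # Powell handles the boundary (near-zero variance components) best;
    # keep a non-converged fallback only if every optimizer stalls.
    result = fallback = None
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("powell", "lbfgs", None):
            try:
                res = (model.fit(reml=True, method=method, maxiter=500)
                       if method else model.fit(reml=True))
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            if not np.all(np.isfinite(res.fe_params)):
                continue
            if res.converged:
                result = res
                break
            if fallback is None or res.llf > fallback.llf:
                fallback = res
        if result is None:
            result = fallback
        if result is None:
            raise FitError(f"mixed model failed to fit: {last_err}")
    return PhenoLMM(
        result=result,
        design_info=model.data.design_info,
        data=df,
        response=response,
        n_obs=len(df),
        rank=rank,
        n_sites=df["site"].nunique(),
        n_ecoregions=df["ecoregion"].nunique(),
    )


def fit_fp_lmm(fp_long: pd.DataFrame, months=GROWING_SEASON) -> PhenoLMM:
    """Fit the FP mixed model for one subset's long table.

    Expects columns ``fp_pct, month, ecoregion, trt_N, trt_P, trt_K,
    site, block``; observations are restricted to the growing-season
    months before fitting. FP is modeled on the percent scale.
    """
    df = fp_long[fp_long["month"].isin(months)].copy()
    df["month"] = df["month"].astype(int)
    for col in ("trt_N", "trt_P", "trt_K"):
        df[col] = df[col].astype(int)
    return _fit_mixed(df, f"fp_pct ~ {FP_RHS}", "fp_pct")


def fit_volume_lmm(volumes: pd.DataFrame) -> tuple[PhenoLMM, pd.DataFrame]:
    """Fit the flowering-volume mixed model (no month factor) and its F table."""
    df = volumes.copy()
    for col in ("trt_N", "trt_P", "trt_K"):
        df[col] = df[col].astype(int)
    handle = _fit_mixed(df, f"volume_pct_month ~ {VOLUME_RHS}", "volume_pct_month")
    return handle, anova_table(handle)


def _term_label(term_name: str) -> str:
    if term_name == "Intercept":
        return "Intercept"
    return " * ".join(FACTOR_LABELS[f] for f in term_name.split(":"))


def _term_sort_key(label: str):
    if label == "Intercept":
        return (0, ())
    factors = label.split(" * ")
    ranks = sorted((_FACTOR_RANK[f] for f in factors), reverse=True)
    return (len(factors), tuple(ranks))


def anova_table(handle: PhenoLMM) -> pd.DataFrame:
    """Marginal (each-term-last) Wald F tests for every fixed-effect term.

    Returns columns ``term, ndf, ddf, F, p`` in the canonical order:
    main effects (P, K+u, N, Month, Ecoregion), then interactions of
    increasing order.
    """
    beta = np.asarray(handle.result.fe_params)
    V = handle.fe_cov()
    rows = []
    for term_name, sl in handle.design_info.term_name_slices.items():
        label = _term_label(term_name)
        idx = np.arange(sl.start, sl.stop)
        b = beta[idx]
        Vt = V[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(Vt, b) / q)
        ddf = handle.ddf_site if label == "Ecoregion" else handle.ddf_residual
        p = float(st.f.sf(F, q, ddf)) if ddf > 0 else np.nan
        rows.append({"term": label, "ndf": q, "ddf": ddf, "F": F, "p": p})
    out = pd.DataFrame(rows)
    return (
        out.assign(_key=out["term"].map(_term_sort_key))
        .sort_values("_key", kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )


def bonferroni(p_raw, m: int | None = None):
    """Bonferroni adjustment: min(1, m * p) over the contrast family."""
    p = np.asarray(p_raw, dtype=float)
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p), m


def significance_stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def _cell_grid(handle: PhenoLMM, with_month: bool) -> pd.DataFrame:
    df = handle.data
    factors = {
        "trt_P": sorted(df["trt_P"].unique()),
        "trt_K": sorted(df["trt_K"].unique()),
        "trt_N": sorted(df["trt_N"].unique()),
        "ecoregion": sorted(df["ecoregion"].unique()),
    }
    if with_month:
        factors["month"] = sorted(df["month"].unique())
    names = list(factors)
    return pd.DataFrame(
        list(itertools.product(*factors.values())), columns=names
    )


def n_by_month_contrasts(handle: PhenoLMM, by_ecoregion: bool = False) -> pd.DataFrame:
    """Model-based N_added - N_free mean differences by month.

    Cell means are averaged over the P and K levels (and over ecoregions
    when pooled). Raw p-values use the residual-stratum t distribution;
    the Bonferroni family is the set of contrasts produced by this call
    (6 pooled, 18 by ecoregion). Estimates are on the percent scale.
    """
    grid = _cell_grid(handle, with_month=True)
    (X,) = patsy.build_design_matrices([handle.design_info], grid)
    X = np.asarray(X)
    beta = np.asarray(handle.result.fe_params)
    V = handle.fe_cov()
    ddf = handle.ddf_residual

    months = sorted(grid["month"].unique())
    ecos = sorted(grid["ecoregion"].unique()) if by_ecoregion else [None]
    rows = []
    for eco in ecos:
        for month in months:
            sel = grid["month"] == month
            if eco is not None:
                sel &= grid["ecoregion"] == eco
            hi = X[(sel & (grid["trt_N"] == 1)).to_numpy()].mean(axis=0)
            lo = X[(sel & (grid["trt_N"] == 0)).to_numpy()].mean(axis=0)
            L = hi - lo
            est = float(L @ beta)
            se = float(np.sqrt(L @ V @ L))
            t = est / se if se > 0 else np.nan
            p = float(2 * st.t.sf(abs(t), ddf)) if np.isfinite(t) else np.nan
            rows.append(
                {"ecoregion": eco if eco is not None else "pooled",
                 "month": month, "estimate": est, "SE": se, "p_raw": p}
            )
    out = pd.DataFrame(rows)
    out["p_adj"], m = bonferroni(out["p_raw"])
    out["m"] = m
    out["stars"] = out["p_adj"].map(significance_stars)
    return out
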