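"""Cohort-level inference: paired tests, adjusted regressions, FDR.

The model battery mirrors a standard radiomics association analysis:

* paired t-tests comparing each textural feature between WMH and NAWM;
* ordinary least squares regressions of (i) WMH volume and (ii) reaction
  time on each textural feature, adjusting for age and sex, with
  Benjamini-Hochberg FDR applied to families (i) and (ii) separately;
* WMH volume x texture interaction models for reaction time, with an
  estimated-marginal-means grid at mean +/- 1 SD of each moderator;
* regressions of the dementia risk score on each feature;
* an exploratory battery regressing each feature jointly on sex, age,
  education, diabetes, smoking and hypertension;
* per-layer re-runs of significant WMH-texture associations over 11 ROIs
  (the WMH itself plus 10 peri-WMH layers), FDR per association.

Continuous predictors are mean-centred before fitting (binary 0/1 columns
are left as coded; sex is coded female = 1).  Missing feature values (e.g.
subjects without lesions) are dropped listwise per model, pairwise for
Spearman correlations.  Classical (non-robust) OLS standard errors are
used throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .texture import SECOND_ORDER_FEATURES, TEXTURE_FEATURES

__all__ = ["PairedResult", "ModelResult", "paired_compare",
           "adjusted_regression", "interaction_regression",
           "spearman_matrix", "fdr_adjust", "run_model_battery",
           "BatteryResults", "ROI_FEATURES"]

#: the twelve ROI-level texture columns the batteries analyse
ROI_FEATURES = tuple(f"{roi}_{f}" for roi in ("WMHT", "NAWMT")
                     for f in TEXTURE_FEATURES)


@dataclasses.dataclass
class PairedResult:
    t: float
    df: int
    p: float
    n: int
    mean_diff: float
    degenerate: bool = False


def paired_compare(table: pd.DataFrame, col_a: str, col_b: str) -> PairedResult:
    """Two-sided paired t-test between two feature columns.

    Pairs with a missing member are dropped.  A zero-variance nonzero
    difference is reported as degenerate (t = +/-inf, p = 0) rather than
    crashing; identical columns give t = 0, p = 1.
    """
    for c in (col_a, col_b):
        if c not in table.columns:
            raise KeyError(f"column '{c}' not in table")
    sub = table[[col_a, col_b]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    d = sub[col_a].to_numpy() - sub[col_b].to_numpy()
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedResult(0.0, n - 1, 1.0, n, 0.0)
        return PairedResult(float(np.sign(d.mean()) * np.inf), n - 1, 0.0, n,
                            float(d.mean()), degenerate=True)
    res = sps.ttest_rel(sub[col_a], sub[col_b])
    return PairedResult(float(res.statistic), n - 1, float(res.pvalue), n,
                        float(d.mean()))


@dataclasses.dataclass
class ModelResult:
    """Fitted-OLS summary: one row per term in ``terms``."""

    outcome: str
    formula: str
    terms: pd.DataFrame          # term, estimate, se, t, p
    n_used: int
    marginal_means: pd.DataFrame | None = None

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term '{name}' in model for {self.outcome}")
        return row.iloc[0]


def _is_binary(s: pd.Series) -> bool:
    vals = set(pd.unique(s.dropna()))
    return vals <= {0, 1, 0.0, 1.0, False, True}


def _fit_ols(df: pd.DataFrame, outcome: str, rhs: list[str],
             center: bool = True, products: list[tuple[str, str]] = ()
             ) -> ModelResult:
    """Centre continuous predictors, optionally add products, fit OLS."""
    work = df.dropna().copy()
    n = len(work)
    X = pd.DataFrame(index=work.index)
    for c in rhs:
        col = work[c].astype(float)
        if center and not _is_binary(col):
            col = col - col.mean()
        X[c] = col
    for a, b in products:
        X[f"{a}:{b}"] = X[a] * X[b]
    n_terms = X.shape[1] + 1
    if n <= n_terms + 2:
        raise ValueError(f"too few observations (n={n}) for {n_terms} terms")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = [c for c in X.columns if X[c].std() == 0]
        raise ValueError("rank-deficient design; collinear or constant "
                         f"terms (suspects: {bad or list(X.columns)})")
    fit = sm.OLS(work[outcome].astype(float), Xc).fit()
    terms = pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    }).reset_index(drop=True)
    formula = f"{outcome} ~ " + " + ".join(Xc.columns.drop("const"))
    return ModelResult(outcome, formula, terms, n)


def adjusted_regression(table: pd.DataFrame, outcome: str, predictor: str,
                        covariates: tuple[str, ...] = ("age", "sex"),
                        extra_covariates: tuple[str, ...] = ()) -> ModelResult:
    """OLS of ``outcome`` on a predictor adjusting for covariates."""
    cols = [outcome, predictor, *covariates, *extra_covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    return _fit_ols(table[cols], outcome,
                    [predictor, *covariates, *extra_covariates])


def interaction_regression(table: pd.DataFrame, outcome: str, a: str, b: str,
                           covariates: tuple[str, ...] = ("age", "sex")
                           ) -> ModelResult:
    """Model ``outcome ~ a + b + a:b + covariates`` with centred a, b.

    The product is formed after mean-centring, so the interaction t is
    invariant to location shifts of either moderator.  A marginal-means
    grid (predicted outcome at mean and mean +/- 1 SD of both moderators,
    covariates at their means) is attached for interaction plots.
    """
    cols = [outcome, a, b, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    res = _fit_ols(table[cols], outcome, [a, b, *covariates],
                   products=[(a, b)])
    work = table[cols].dropna()
    sa, sb = work[a].std(), work[b].std()
    est = dict(zip(res.terms["term"], res.terms["estimate"]))
    rows = []
    for la, lev_a in (("low", -sa), ("moderate", 0.0), ("high", sa)):
        for lb, lev_b in (("low", -sb), ("moderate", 0.0), ("high", sb)):
            pred = (est["const"] + est[a] * lev_a + est[b] * lev_b
                    + est[f"{a}:{b}"] * lev_a * lev_b)
            rows.append({f"{a}_level": la, f"{b}_level": lb,
                         "predicted": pred})
    res.marginal_means = pd.DataFrame(rows)
    return res


def spearman_matrix(table: pd.DataFrame, features: list[str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p with pairwise deletion.

    Constant columns (no rank variation) yield NaN entries.
    """
    k = len(features)
    rho = pd.DataFrame(np.eye(k), index=features, columns=features)
    pval = pd.DataFrame(np.zeros((k, k)), index=features, columns=features)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[features[i], features[j]]].dropna()
            if len(sub) < 3 or sub.iloc[:, 0].nunique() < 2 \
                    or sub.iloc[:, 1].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


def fdr_adjust(p_values, q: float = 0.05
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclasses.dataclass
class BatteryResults:
    """Tidy battery output: one row per model term, plus marginal means."""

    results: pd.DataFrame
    marginal_means: dict[str, pd.DataFrame]


def _collect(rows: list[dict], battery: str, family: str, res: ModelResult,
             focal: str) -> None:
    for _, r in res.terms.iterrows():
        rows.append({
            "battery": battery, "family": family, "outcome": res.outcome,
            "predictor": focal, "term": r["term"], "estimate": r["estimate"],
            "se": r["se"], "t": r["t"], "p": r["p"],
            "focal": r["term"] == focal, "n": res.n_used,
            "formula": res.formula,
        })


def run_model_battery(table: pd.DataFrame, fdr_q: float = 0.05,
                     n_layers: int = 10) -> BatteryResults:
    """Run the full association battery on a cohort feature table.

    Requires the twelve ROI texture columns, ``wmh_pct_etiv_cuberoot``,
    ``reaction_time_ms``, ``risk_score`` and the covariate columns; layer
    batteries run when ``layer{k}_*`` columns are present.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    required = [*ROI_FEATURES, "wmh_pct_etiv_cuberoot", "reaction_time_ms",
                "risk_score", "age", "sex"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    rows: list[dict] = []
    mmeans: dict[str, pd.DataFrame] = {}

    # (a) texture -> WMH volume, (b) texture -> reaction time,
    # (d) texture -> risk score: one family each
    for family, outcome in (("wmh_volume", "wmh_pct_etiv_cuberoot"),
                            ("reaction_time", "reaction_time_ms"),
                            ("risk_score", "risk_score")):
        for feat in ROI_FEATURES:
            res = adjusted_regression(table, outcome, feat)
            _collect(rows, "texture_regression", family, res, feat)
    # WMH volume -> reaction time (its own single-test family)
    res = adjusted_regression(table, "reaction_time_ms",
                              "wmh_pct_etiv_cuberoot")
    _collect(rows, "texture_regression", "wmhvol_to_rt", res,
             "wmh_pct_etiv_cuberoot")

    # (c) WMH volume x texture interactions for reaction time
    for feat in ROI_FEATURES:
        res = interaction_regression(table, "reaction_time_ms",
                                     "wmh_pct_etiv_cuberoot", feat)
        focal = f"wmh_pct_etiv_cuberoot:{feat}"
        _collect(rows, "interaction", "interaction_rt", res, focal)
        mmeans[feat] = res.marginal_means

    # (e) exploratory risk-factor battery (joint predictors)
    rf_cols = ("sex", "age", "education_years", "diabetes", "smoking",
               "hypertension")
    if all(c in table.columns for c in rf_cols):
        for feat in ROI_FEATURES:
            try:
                res = _fit_ols(table[[feat, *rf_cols]], feat, list(rf_cols))
            except ValueError:
                continue  # e.g. no variation in a risk factor at small n
            for rf in rf_cols:
                for _, r in res.terms[res.terms["term"] == rf].iterrows():
                    rows.append({
                        "battery": "risk_factors", "family": f"rf_{rf}",
                        "outcome": feat, "predictor": rf, "term": rf,
                        "estimate": r["estimate"], "se": r["se"],
                        "t": r["t"], "p": r["p"], "focal": True,
                        "n": res.n_used, "formula": res.formula})

    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for fam, grp in out.groupby("family"):
        focal_idx = grp.index[grp["focal"]]
        if len(focal_idx):
            adj, _rej = fdr_adjust(out.loc[focal_idx, "p"].to_numpy(), fdr_q)
            out.loc[focal_idx, "p_fdr"] = adj

    # (f) per-layer re-runs of FDR-significant WMH-texture associations
    layer_cols_exist = any(f"layer1_{f}" in table.columns
                           for f in TEXTURE_FEATURES)
    if layer_cols_exist:
        sig = out[(out["battery"] == "texture_regression")
                  & out["family"].isin(["wmh_volume", "reaction_time"])
                  & out["focal"] & (out["p_fdr"] < fdr_q)
                  & out["predictor"].str.startswith("WMHT_")]
        layer_rows: list[dict] = []
        for _, srow in sig.iterrows():
            base = srow["predictor"].removeprefix("WMHT_")
            outcome = srow["outcome"]
            assoc = f"layers::{srow['predictor']}->{outcome}"
            roi_cols = [srow["predictor"]] + [
                f"layer{k}_{base}" for k in range(1, n_layers + 1)
                if f"layer{k}_{base}" in table.columns]
            for roi_col in roi_cols:
                try:
                    res = adjusted_regression(table, outcome, roi_col)
                except (ValueError, KeyError):
                    continue
                r = res.term(roi_col)
                layer_rows.append({
                    "battery": "layers", "family": assoc, "outcome": outcome,
                    "predictor": roi_col, "term": roi_col,
                    "estimate": r["estimate"], "se": r["se"], "t": r["t"],
                    "p": r["p"], "focal": True, "n": res.n_used,
                    "formula": res.formula})
        if layer_rows:
            lay = pd.DataFrame(layer_rows)
            lay["p_fdr"] = np.nan
            for fam, grp in lay.groupby("family"):
                adj, _rej = fdr_adjust(grp["p"].to_numpy(), fdr_q)
                lay.loc[grp.index, "p_fdr"] = adj
            out = pd.concat([out, lay], ignore_index=True)

    return BatteryResults(out, mmeans)
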