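"""Three-stage group statistics for tract MTR and MTRh tables.

Stage 1 tests each metric (8 tract MTRs and MTRh, aggregated per subject
over levels) with a one-way ANOVA on clinical outcome. Stage 2, triggered
per metric by stage-1 significance, refits with outcome and sex as crossed
factors (Type III sums of squares). Stage 3 fits a linear mixed model on the
slice-level (or tract-level) long table — fixed effects for outcome, sex,
their interaction, BMI, age and intervertebral level (plus tract and side
for MTR), a random intercept per subject — and reports least-square means
per outcome x sex cell with pairwise contrasts, optionally pooling over
multiply-imputed datasets by Rubin's rules. Pearson correlations of each
metric with the year-1 Neck Disability Index (NDI) are computed per level.

Outcome classification follows the NDI bands: recovered (NDI < 10%), mild
(NDI 10-28%), severe (NDI > 28%); both boundaries are read as mild.
Significance threshold is alpha = 0.05 throughout, with Bonferroni-adjusted
post-hoc comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

OUTCOMES = ("recovered", "mild", "severe")
SEXES = ("female", "male")
ALPHA = 0.05


def classify_outcome(ndi_year1_pct: float, boundary_policy: str = "mild") -> str:
    """Classify 1-year outcome from the NDI% score.

    recovered: NDI < 10; mild: 10 <= NDI <= 28; severe: NDI > 28. With the
    default policy both interval boundaries (10 and 28) belong to ``mild``.
    """
    ndi = float(ndi_year1_pct)
    if not (0.0 <= ndi <= 100.0) or not np.isfinite(ndi):
        raise ValueError(f"NDI must lie in [0, 100], got {ndi}")
    if boundary_policy != "mild":
        raise ValueError("only the 'mild' boundary policy is implemented")
    if ndi < 10.0:
        return "recovered"
    if ndi <= 28.0:
        return "mild"
    return "severe"


def aggregate_subject_level(
    tract_table: pd.DataFrame, mtrh_records: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject means over available levels, one column per metric.

    Produces the subject-level table feeding the stage-1/2 ANOVAs: one row
    per subject, columns for each tract's mean MTR and for mean MTRh.
    """
    wide = (
        tract_table.pivot_table(
            index=["subject_id", "level"], columns="tract", values="mtr_percent"
        )
        .groupby("subject_id")
        .mean()
    )
    wide.columns.name = None
    mh = mtrh_records.groupby("subject_id")["mtrh"].mean()
    return wide.join(mh, how="outer").reset_index()


@dataclass
class AnalysisResult:
    """Result container for one statistical model.

    Holds the ANOVA table (``anova``), Bonferroni post-hoc contrasts
    (``posthoc``), least-square means and cell contrasts for mixed models
    (``ls_means``, ``contrasts``), correlation tables (``correlations``) and
    any quality flags. ``summary()`` renders a plain-text report section.
    """

    model_id: str
    anova: Optional[pd.DataFrame] = None
    posthoc: Optional[pd.DataFrame] = None
    ls_means: Optional[pd.DataFrame] = None
    contrasts: Optional[pd.DataFrame] = None
    correlations: Optional[pd.DataFrame] = None
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        parts = [f"== {self.model_id} =="]
        for name in ("anova", "posthoc", "ls_means", "contrasts", "correlations"):
            tbl = getattr(self, name)
            if tbl is not None and len(tbl):
                parts.append(f"-- {name} --")
                parts.append(tbl.to_string(float_format=lambda v: f"{v:.6g}"))
        if self.flags:
            parts.append("flags: " + ", ".join(self.flags))
        return "\n".join(parts) + "\n"


def _pairwise_bonferroni(
    df: pd.DataFrame,
    value_col: str,
    cell_col: str,
    mse: float,
    df_resid: float,
) -> pd.DataFrame:
    """Pairwise cell contrasts with a pooled error term, Bonferroni adjusted."""
    cells = list(df[cell_col].dropna().unique())
    k = len(cells)
    n_comp = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(cells, 2):
        xa = df.loc[df[cell_col] == a, value_col].dropna()
        xb = df.loc[df[cell_col] == b, value_col].dropna()
        diff = xa.mean() - xb.mean()
        se = np.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
        t = diff / se if se > 0 else np.nan
        p_raw = 2 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
        tcrit = sps.t.ppf(1 - ALPHA / 2, df_resid)
        rows.append(
            {
                "comparison": f"{a}:{b}",
                "mean_difference": diff,
                "ci_lower": diff - tcrit * se,
                "ci_upper": diff + tcrit * se,
                "se": se,
                "t": t,
                "p_raw": p_raw,
                "p_adj": min(p_raw * n_comp, 1.0) if np.isfinite(p_raw) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def anova_oneway(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "outcome",
    posthoc_alpha: float = ALPHA,
) -> AnalysisResult:
    """One-way ANOVA of a subject-level metric on clinical outcome.

    Returns the standard decomposition (sum of squares, df, F, p) and, when
    the omnibus test is significant, Bonferroni-adjusted pairwise group
    contrasts using the pooled residual error.
    """
    df = data[[group_col, value_col]].dropna()
    counts = df.groupby(group_col)[value_col].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 subjects")
    for g, n in counts.items():
        if n <= 1 and df.loc[df[group_col] == g, value_col].var(ddof=0) == 0:
            raise ValueError(f"group {g!r} has n <= 1")
    model = smf.ols(f"Q('{value_col}') ~ C(Q('{group_col}'))", data=df).fit()
    table = anova_lm(model, typ=1)
    table = table.rename(
        index={
            f"C(Q('{group_col}'))": group_col,
            "Residual": "residual",
        }
    )
    p = float(table.loc[group_col, "PR(>F)"])
    posthoc = None
    if p < posthoc_alpha:
        posthoc = _pairwise_bonferroni(
            df, value_col, group_col, model.mse_resid, model.df_resid
        )
    return AnalysisResult(model_id=f"oneway:{value_col}", anova=table, posthoc=posthoc)


def anova_twoway(
    data: pd.DataFrame,
    value_col: str,
    factors: tuple[str, str] = ("outcome", "sex"),
    posthoc_alpha: float = ALPHA,
) -> AnalysisResult:
    """Two-way ANOVA with main effects and interaction (Type III SS).

    Factors are sum-coded so Type III sums of squares are well defined on the
    unbalanced design. On a significant interaction (or main effect) the
    post-hoc compares the factor-combination cells pairwise with Bonferroni
    adjustment.
    """
    fa, fb = factors
    df = data[[fa, fb, value_col]].dropna().copy()
    if df[fb].nunique() < 2:
        return anova_oneway(df, value_col, group_col=fa, posthoc_alpha=posthoc_alpha)
    n_cells = df.groupby([fa, fb]).ngroups
    if len(df) - n_cells < 1:
        raise ValueError(
            "two-way ANOVA needs residual degrees of freedom "
            f"(n={len(df)}, cells={n_cells})"
        )
    formula = (
        f"Q('{value_col}') ~ C(Q('{fa}'), Sum) + C(Q('{fb}'), Sum) "
        f"+ C(Q('{fa}'), Sum):C(Q('{fb}'), Sum)"
    )
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=3)
    rename = {
        f"C(Q('{fa}'), Sum)": fa,
        f"C(Q('{fb}'), Sum)": fb,
        f"C(Q('{fa}'), Sum):C(Q('{fb}'), Sum)": f"{fa}*{fb}",
        "Residual": "residual",
    }
    table = table.rename(index=rename)
    table = table.drop(index=[i for i in table.index if i == "Intercept"])
    any_sig = (table.loc[[fa, fb, f"{fa}*{fb}"], "PR(>F)"] < posthoc_alpha).any()
    posthoc = None
    if any_sig:
        df["_cell"] = df[fa].astype(str) + "/" + df[fb].astype(str)
        posthoc = _pairwise_bonferroni(
            df, value_col, "_cell", model.mse_resid, model.df_resid
        )
    return AnalysisResult(model_id=f"twoway:{value_col}", anova=table, posthoc=posthoc)


# --- stage 3: linear mixed model with LS-means ------------------------------


def _lsmeans_design(design_info, data: pd.DataFrame, nuisance: dict) -> pd.DataFrame:
    """Prediction grid over outcome x sex cells averaging nuisance factors."""
    cells = []
    for outcome in OUTCOMES:
        for sex in SEXES:
            grid = {"outcome": [outcome], "sex": [sex]}
            grid.update({k: list(v) for k, v in nuisance.items()})
            frame = pd.DataFrame(
                list(itertools.product(*grid.values())), columns=list(grid.keys())
            )
            (exog,) = patsy.build_design_matrices([design_info], frame)
            cells.append(
                {"outcome": outcome, "sex": sex, "L": np.asarray(exog).mean(axis=0)}
            )
    return pd.DataFrame(cells)


_CONTRAST_SET = (
    ("recovered", "mild", "male"),
    ("recovered", "severe", "male"),
    ("mild", "severe", "male"),
    ("recovered", "mild", "female"),
    ("recovered", "severe", "female"),
    ("mild", "severe", "female"),
)


def fit_mixed_model(
    long_table: pd.DataFrame,
    response: str = "mtrh",
    value_col: str = "value",
    extra_factors: Sequence[str] = (),
) -> AnalysisResult:
    """Linear mixed model with LS-means per outcome x sex cell.

    Fixed effects: outcome, sex, outcome x sex, BMI, age and intervertebral
    level, plus any ``extra_factors`` (tract and side for the MTR model);
    random intercept per subject. LS-means evaluate the fixed-effect design
    at covariate means, averaging over levels (and extra factors), with 95%
    Wald confidence intervals; contrasts compare cells within sex, across
    sex, and report Wald p-values. A singular or non-converging fit falls
    back to OLS on the same fixed effects, flagged ``ols_fallback``.
    """
    df = long_table.dropna(subset=[value_col, "outcome", "sex", "bmi", "age", "level"]).copy()
    if not len(df):
        raise ValueError("empty table after dropping missing rows")
    terms = ["C(outcome)", "C(sex)", "C(outcome):C(sex)", "bmi", "age", "C(level)"]
    terms += [f"C({f})" for f in extra_factors]
    formula = f"{value_col} ~ " + " + ".join(terms)

    flags: list[str] = []
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(formula, df, groups=df["subject_id"])
            fit = md.fit(reml=True, method=["lbfgs", "powell"])
            if not fit.converged or not np.all(np.isfinite(fit.bse_fe)):
                raise RuntimeError("mixed model did not converge")
        except Exception:
            fit = None
    if fit is None:
        ols = smf.ols(formula, df).fit()
        params = ols.params
        cov = ols.cov_params()
        design_info = ols.model.data.design_info
        flags.append("ols_fallback")
    else:
        params = fit.fe_params
        k = len(params)
        cov = fit.cov_params().iloc[:k, :k]
        design_info = fit.model.data.design_info

    nuisance = {"bmi": [df["bmi"].mean()], "age": [df["age"].mean()], "level": sorted(df["level"].unique())}
    for f in extra_factors:
        nuisance[f] = sorted(df[f].unique())
    cells = _lsmeans_design(design_info, df, nuisance)

    P = np.asarray(params, dtype=float)
    C = np.asarray(cov, dtype=float)
    z = sps.norm.ppf(1 - ALPHA / 2)
    n_per_cell = df.groupby(["outcome", "sex"])["subject_id"].nunique()
    ls_rows = []
    for _, row in cells.iterrows():
        L = row["L"]
        est = float(L @ P)
        se = float(np.sqrt(L @ C @ L))
        ls_rows.append(
            {
                "outcome": row["outcome"],
                "sex": row["sex"],
                "n": int(n_per_cell.get((row["outcome"], row["sex"]), 0)),
                "estimate": est,
                "ci_lower": est - z * se,
                "ci_upper": est + z * se,
                "se": se,
            }
        )
    ls_means = pd.DataFrame(ls_rows)

    def _L(outcome, sex):
        return cells.loc[
            (cells["outcome"] == outcome) & (cells["sex"] == sex), "L"
        ].iloc[0]

    contrast_rows = []
    for a, b, sex in _CONTRAST_SET:
        contrast_rows.append((f"{a} vs {b}", sex, _L(a, sex) - _L(b, sex)))
    for outcome in OUTCOMES:
        contrast_rows.append(
            ("male vs female", outcome, _L(outcome, "male") - _L(outcome, "female"))
        )
    crows = []
    for name, within, Ld in contrast_rows:
        est = float(Ld @ P)
        se = float(np.sqrt(Ld @ C @ Ld))
        pval = 2 * sps.norm.sf(abs(est / se)) if se > 0 else np.nan
        crows.append(
            {
                "comparison": name,
                "within": within,
                "estimate": est,
                "ci_lower": est - z * se,
                "ci_upper": est + z * se,
                "p": pval,
            }
        )
    contrasts = pd.DataFrame(crows)

    # Wald chi-square test of the outcome x sex interaction block
    inter_ix = [
        i for i, n in enumerate(params.index) if "C(outcome)" in n and "C(sex)" in n
    ]
    anova_tbl = None
    if inter_ix:
        R = np.zeros((len(inter_ix), len(P)))
        for r, i in enumerate(inter_ix):
            R[r, i] = 1.0
        est = R @ P
        V = R @ C @ R.T
        try:
            w = float(est @ np.linalg.solve(V, est))
            p_int = float(sps.chi2.sf(w, len(inter_ix)))
        except np.linalg.LinAlgError:
            w, p_int = np.nan, np.nan
        anova_tbl = pd.DataFrame(
            [{"term": "outcome*sex", "wald_chi2": w, "df": len(inter_ix), "p": p_int}]
        ).set_index("term")

    return AnalysisResult(
        model_id=f"mixed:{response}",
        anova=anova_tbl,
        ls_means=ls_means,
        contrasts=contrasts,
        flags=flags,
    )


# --- multiple imputation ----------------------------------------------------


def impute_missing(
    long_table: pd.DataFrame,
    value_col: str = "value",
    n_sets: int = 5,
    seed: int = 0,
    cell_cols: tuple[str, str] = ("outcome", "sex"),
    covariates: Sequence[str] = ("age", "bmi"),
) -> list[pd.DataFrame]:
    """Multiple imputation of missing metric values (default 5 sets).

    Scheme: within each outcome x sex cell, regress the observed values on
    the covariates plus level indicators, then fill each missing value with
    the model prediction plus a residual resampled (with replacement) from
    the cell's observed residuals — a simple proper-variability scheme whose
    per-set fits are pooled by Rubin's rules via :func:`pool_rubin`. Cells
    with more than 50% missing are refused with a diagnostic. A table with
    no missing values returns ``n_sets`` identical copies.
    """
    df = long_table.copy()
    missing = df[value_col].isna()
    for cell, grp in df.groupby(list(cell_cols)):
        frac = grp[value_col].isna().mean()
        if frac > 0.5:
            raise ValueError(
                f"cell {cell} has {frac:.0%} missing values (> 50%); refusing to impute"
            )
    if not missing.any():
        return [df.copy() for _ in range(n_sets)]

    rng = np.random.default_rng(seed)

    # design built over the full table so every level is representable even
    # when a cell's observed rows miss some category
    design_cols = [c for c in covariates if c in df.columns]
    X_all = df[design_cols].astype(float) if design_cols else pd.DataFrame(index=df.index)
    if "level" in df.columns:
        X_all = pd.concat(
            [X_all, pd.get_dummies(df["level"], prefix="level", drop_first=True, dtype=float)],
            axis=1,
        )
    X_all.insert(0, "const", 1.0)
    X_all = X_all.to_numpy(dtype=float)
    y_all = df[value_col].to_numpy(dtype=float)

    def fit_predict(train_ix, pred_ix):
        Xt, yt = X_all[train_ix], y_all[train_ix]
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta
        return X_all[pred_ix] @ beta, resid

    pos = {ix: i for i, ix in enumerate(df.index)}
    sets = []
    for _ in range(n_sets):
        filled = df.copy()
        for cell, grp in df.groupby(list(cell_cols)):
            miss = grp[grp[value_col].isna()]
            if not len(miss):
                continue
            obs = grp.dropna(subset=[value_col])
            train = obs if len(obs) >= 8 else df.dropna(subset=[value_col])
            train_ix = [pos[i] for i in train.index]
            pred_ix = [pos[i] for i in miss.index]
            pred, resid = fit_predict(train_ix, pred_ix)
            draw = resid[rng.integers(0, len(resid), size=len(miss))]
            filled.loc[miss.index, value_col] = pred + draw
        sets.append(filled)
    return sets


def pool_rubin(estimates: np.ndarray, variances: np.ndarray) -> pd.DataFrame:
    """Pool per-set estimates and variances by Rubin's rules.

    ``estimates`` and ``variances`` are (m_sets, k_params) arrays. Returns
    pooled estimates with total variance (within + (1 + 1/m) between),
    standard errors, Barnard-Rubin-style degrees of freedom and p-values.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    m = est.shape[0]
    qbar = est.mean(axis=0)
    ubar = var.mean(axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = ubar + (1 + 1 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * b / ubar
        dof = np.where(b > 0, (m - 1) * (1 + 1 / r) ** 2, np.inf)
    se = np.sqrt(total)
    t = qbar / se
    p = 2 * sps.t.sf(np.abs(t), np.where(np.isfinite(dof), dof, 1e6))
    return pd.DataFrame(
        {"estimate": qbar, "se": se, "df": dof, "p": p, "within_var": ubar, "between_var": b}
    )


def pearson_ndi(
    metric_long: pd.DataFrame,
    ndi: pd.Series,
    value_col: str = "value",
    metric_col: str = "metric",
) -> pd.DataFrame:
    """Pearson correlation of each metric with year-1 NDI%, per level.

    ``metric_long`` has columns subject_id, level, ``metric_col`` and
    ``value_col``; ``ndi`` maps subject_id to NDI%. A constant metric yields
    a missing r with a ``constant_metric`` flag.
    """
    rows = []
    for (level, metric), grp in metric_long.groupby(["level", metric_col]):
        merged = grp.dropna(subset=[value_col]).set_index("subject_id")
        x = merged[value_col]
        y = ndi.reindex(x.index)
        ok = x.notna() & y.notna()
        x, y = x[ok], y[ok]
        if len(x) < 3 or x.nunique() <= 1 or y.nunique() <= 1:
            rows.append(
                {"level": level, "metric": metric, "r": np.nan, "p": np.nan,
                 "n": int(len(x)), "flag": "constant_metric"}
            )
            continue
        r, p = sps.pearsonr(x, y)
        rows.append(
            {"level": level, "metric": metric, "r": float(r), "p": float(p),
             "n": int(len(x)), "flag": "ok"}
        )
    return pd.DataFrame(rows)


# --- orchestration ----------------------------------------------------------


@dataclass
class StagedAnalysis:
    """All results of the three-stage analysis plus the text report."""

    stage1: dict[str, AnalysisResult]
    stage2: dict[str, AnalysisResult]
    stage3: dict[str, AnalysisResult]
    correlations: pd.DataFrame
    report: str


def run_staged_analysis(
    subjects: pd.DataFrame,
    tract_table: pd.DataFrame,
    mtrh_records: pd.DataFrame,
    gate: bool = True,
    alpha: float = ALPHA,
    n_imputations: int = 5,
    seed: int = 0,
) -> StagedAnalysis:
    """Run the full three-stage analysis on processed pipeline tables.

    Stage-2 models run only for metrics whose stage-1 ANOVA is significant
    (``gate=False`` runs them all). Stage 3 fits the mixed models for MTRh
    (slice-level) and MTR (tract-level, with tract and side factors); when
    quality-rejected slices left missing values, they are multiply imputed
    and the LS-means pooled by Rubin's rules is left to the per-set fits'
    average (reported per fit in the report).
    """
    subj = subjects.set_index("subject_id")
    per_subject = aggregate_subject_level(tract_table, mtrh_records)
    per_subject = per_subject.merge(
        subjects[["subject_id", "outcome", "sex", "age", "bmi", "ndi_year1_pct"]],
        on="subject_id",
    )
    metrics = [c for c in per_subject.columns if c.endswith(("_L", "_R"))] + ["mtrh"]

    stage1: dict[str, AnalysisResult] = {}
    for m in metrics:
        if per_subject[m].notna().sum() >= 6:
            stage1[m] = anova_oneway(per_subject, m)

    stage2: dict[str, AnalysisResult] = {}
    for m, res in stage1.items():
        p = float(res.anova.iloc[0]["PR(>F)"])
        if (not gate) or p < alpha:
            try:
                stage2[m] = anova_twoway(per_subject, m)
            except ValueError as exc:
                stage2[m] = AnalysisResult(
                    model_id=f"twoway:{m}", flags=[f"degenerate_design: {exc}"]
                )

    # stage 3: long tables joined to subject covariates
    cov_cols = ["outcome", "sex", "age", "bmi"]
    mtrh_long = mtrh_records.merge(
        subjects[["subject_id"] + cov_cols], on="subject_id"
    ).rename(columns={"mtrh": "value"})
    mtr_long = tract_table.merge(
        subjects[["subject_id"] + cov_cols], on="subject_id"
    ).rename(columns={"mtr_percent": "value"})
    mtr_long["side"] = mtr_long["tract"].str[-1]
    mtr_long["tract_base"] = mtr_long["tract"].str[:-2]

    stage3: dict[str, AnalysisResult] = {}
    for name, table, extra in (
        ("mtrh", mtrh_long, ()),
        ("mtr", mtr_long, ("tract_base", "side")),
    ):
        if table["value"].isna().any():
            sets = impute_missing(table, n_sets=n_imputations, seed=seed)
            fits = [fit_mixed_model(s, response=name, extra_factors=extra) for s in sets]
            pooled = _pool_lsmeans(fits)
            pooled.model_id = f"mixed:{name} (pooled over {n_imputations} imputations)"
            stage3[name] = pooled
        else:
            stage3[name] = fit_mixed_model(table, response=name, extra_factors=extra)

    metric_long = pd.concat(
        [
            mtrh_long.assign(metric="mtrh")[["subject_id", "level", "metric", "value"]],
            mtr_long.assign(metric=mtr_long["tract"])[
                ["subject_id", "level", "metric", "value"]
            ],
        ]
    )
    corr = pearson_ndi(metric_long, subj["ndi_year1_pct"])

    lines = ["Three-stage MT analysis report", "=" * 32, ""]
    lines.append(f"Stage 1: one-way ANOVA on outcome ({len(stage1)} metrics)")
    for m, res in stage1.items():
        p = float(res.anova.iloc[0]["PR(>F)"])
        star = " *" if p < alpha else ""
        lines.append(f"  {m}: F = {res.anova.iloc[0]['F']:.3f}, p = {p:.4f}{star}")
    lines.append("")
    lines.append(f"Stage 2: outcome x sex ANOVA ({len(stage2)} metrics)")
    for m, res in stage2.items():
        if res.anova is None or "outcome*sex" not in res.anova.index:
            lines.append(f"  {m}: not estimable ({'; '.join(res.flags) or 'n/a'})")
            continue
        p = float(res.anova.loc["outcome*sex", "PR(>F)"])
        lines.append(f"  {m}: interaction p = {p:.4f}{' *' if p < alpha else ''}")
    lines.append("")
    lines.append("Stage 3: linear mixed models")
    for m, res in stage3.items():
        if res.anova is not None and "p" in res.anova.columns:
            p = float(res.anova.iloc[0]["p"])
            lines.append(
                f"  {m}: outcome x sex Wald p = {p:.4f}{' *' if p < alpha else ''}"
            )
        for r in (res,):
            if r.ls_means is not None:
                for _, row in r.ls_means.iterrows():
                    lines.append(
                        f"    LS-mean {row['outcome']}/{row['sex']}: "
                        f"{row['estimate']:.4f} [{row['ci_lower']:.4f}, {row['ci_upper']:.4f}]"
                    )
    lines.append("")
    sig_corr = corr[(corr["flag"] == "ok") & (corr["p"] < alpha)]
    lines.append(f"NDI correlations: {len(sig_corr)} significant of {len(corr)}")
    report = "\n".join(lines) + "\n"

    return StagedAnalysis(
        stage1=stage1, stage2=stage2, stage3=stage3, correlations=corr, report=report
    )


def _pool_lsmeans(fits: list[AnalysisResult]) -> AnalysisResult:
    """Pool LS-means and contrasts from per-imputation fits by Rubin's rules."""
    base = fits[0]
    est = np.stack([f.ls_means["estimate"].to_numpy() for f in fits])
    var = np.stack([f.ls_means["se"].to_numpy() ** 2 for f in fits])
    pooled = pool_rubin(est, var)
    ls = base.ls_means.copy()
    z = sps.norm.ppf(1 - ALPHA / 2)
    ls["estimate"] = pooled["estimate"].to_numpy()
    ls["se"] = pooled["se"].to_numpy()
    ls["ci_lower"] = ls["estimate"] - z * ls["se"]
    ls["ci_upper"] = ls["estimate"] + z * ls["se"]

    cest = np.stack([f.contrasts["estimate"].to_numpy() for f in fits])
    cse = np.stack(
        [
            ((f.contrasts["ci_upper"] - f.contrasts["estimate"]) / z).to_numpy()
            for f in fits
        ]
    )
    cpooled = pool_rubin(cest, cse**2)
    ct = base.contrasts.copy()
    ct["estimate"] = cpooled["estimate"].to_numpy()
    ct["ci_lower"] = ct["estimate"] - z * cpooled["se"].to_numpy()
    ct["ci_upper"] = ct["estimate"] + z * cpooled["se"].to_numpy()
    ct["p"] = cpooled["p"].to_numpy()

    anova_tbl = None
    if base.anova is not None:
        ws = np.array([float(f.anova.iloc[0]["wald_chi2"]) for f in fits])
        dfs = int(base.anova.iloc[0]["df"])
        # simple D1-style combination: average chi2, same df (documented approx.)
        w = float(ws.mean())
        anova_tbl = pd.DataFrame(
            [
                {
                    "term": "outcome*sex",
                    "wald_chi2": w,
                    "df": dfs,
                    "p": float(sps.chi2.sf(w, dfs)),
                }
            ]
        ).set_index("term")

    flags = sorted({fl for f in fits for fl in f.flags} | {"rubin_pooled"})
    return AnalysisResult(
        model_id=base.model_id,
        anova=anova_tbl,
        ls_means=ls,
        contrasts=ct,
        flags=flags,
    )
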