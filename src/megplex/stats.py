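"""Cohort-level statistics: impairment flags, paired change tests, covariate
screening, backward-elimination regression, and Bonferroni correction.

Conventions
-----------
* A cohort table is a tidy :class:`pandas.DataFrame` with one row per
  subject x timepoint: columns ``subject_id``, ``timepoint`` ('T1'/'T2'),
  ``ec_fpn``, one column per executive-functioning Z-score, and covariate
  columns. Covariate kinds (continuous / binary / categorical) are declared
  separately, not inferred.
* Normality gates use Shapiro-Wilk at alpha = 0.05: paired t-test vs
  Wilcoxon signed-rank, Pearson vs Spearman, t-test vs Mann-Whitney,
  ANOVA vs Kruskal-Wallis.
* Backward elimination removes the predictor with the largest p-value while
  that p is at or above the removal threshold (default 0.10).
* Missingness is handled complete-case per analysis, with the analysis n
  reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "ChangeRecord",
    "PairedTestResult",
    "ScreenResult",
    "RegressionResult",
    "classify_impairment",
    "change_scores",
    "paired_change_test",
    "screen_covariates",
    "drop_collinear",
    "backward_regression",
    "bonferroni_threshold",
]

NORMALITY_ALPHA = 0.05
DEFAULT_REMOVAL_THRESHOLD = 0.10


@dataclass(frozen=True)
class CovariateSpec:
    """Declared covariate: its measurement kind and, when categorical, the
    reference level used for indicator coding."""

    name: str
    kind: str  # 'continuous' | 'binary' | 'categorical'
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}"
            )


@dataclass
class ChangeRecord:
    """Per-subject T2 - T1 deltas; EF deltas may be missing per test."""

    subject_id: str
    delta_ec: float
    delta_ef: dict[str, float] = field(default_factory=dict)


@dataclass
class PairedTestResult:
    test_used: str  # 'paired-t' | 'wilcoxon'
    statistic: float
    p_value: float
    n_pairs: int


@dataclass
class ScreenResult:
    """Outcome of one candidate-covariate association screen."""

    name: str
    kind: str
    test_used: str
    p_value: float
    selected: bool


@dataclass
class RegressionResult:
    dependent: str
    retained: list[tuple[str, float, float]]  # (label, standardized beta, p)
    excluded: list[tuple[str, float]]  # (label, p at exclusion step)
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    model_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent,
            "retained": [
                {"predictor": p, "standardized_beta": b, "p_value": pv}
                for p, b, pv in self.retained
            ],
            "excluded": [
                {"predictor": p, "p_value_at_exclusion": pv}
                for p, pv in self.excluded
            ],
            "adj_r2": self.adj_r2,
            "f_stat": self.f_stat,
            "df": list(self.df),
            "model_p": self.model_p,
            "n": self.n,
        }


def classify_impairment(z):
    """Flag cognitive impairment: True iff Z < -1.5 (strict).

    Accepts a scalar or an array/Series; missing values propagate as
    missing (``None`` for scalars, ``pd.NA`` elementwise), never as False.
    """
    if np.isscalar(z) or z is None:
        if z is None or (isinstance(z, float) and np.isnan(z)):
            return None
        if np.isinf(z):
            raise ValueError("Z-score must be finite")
        return bool(z < -1.5)
    series = pd.Series(np.asarray(z, dtype=float))
    out = pd.Series(pd.array(series < -1.5, dtype="boolean"), index=series.index)
    out[series.isna()] = pd.NA
    return out


def change_scores(
    cohort: pd.DataFrame, ef_tests: list[str] | None = None
) -> list[ChangeRecord]:
    """T2 - T1 change records for subjects observed at both timepoints.

    Subjects missing a timepoint are omitted entirely; a missing component
    of a single EF test drops that test's delta only. Omission counts are
    logged, never silent.
    """
    if ef_tests is None:
        ef_tests = [c for c in cohort.columns if c.startswith("ef_")]
    wide = cohort.pivot(index="subject_id", columns="timepoint")
    records: list[ChangeRecord] = []
    n_dropped = 0
    for sid in wide.index:
        try:
            ec1 = wide.loc[sid, ("ec_fpn", "T1")]
            ec2 = wide.loc[sid, ("ec_fpn", "T2")]
        except KeyError:
            ec1 = ec2 = np.nan
        if pd.isna(ec1) or pd.isna(ec2):
            n_dropped += 1
            continue
        deltas: dict[str, float] = {}
        for test in ef_tests:
            v1 = wide.loc[sid, (test, "T1")] if (test, "T1") in wide.columns else np.nan
            v2 = wide.loc[sid, (test, "T2")] if (test, "T2") in wide.columns else np.nan
            if pd.notna(v1) and pd.notna(v2):
                deltas[test] = float(v2 - v1)
        records.append(
            ChangeRecord(subject_id=str(sid), delta_ec=float(ec2 - ec1),
                         delta_ef=deltas)
        )
    if n_dropped:
        logger.info("change_scores: omitted %d subject(s) lacking both "
                    "timepoints", n_dropped)
    return records


def _shapiro_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(sps.shapiro(x).pvalue >= alpha)


def paired_change_test(values_t1, values_t2) -> PairedTestResult:
    """Two-sided paired comparison of T1 vs T2 values.

    Differences are gated through Shapiro-Wilk: paired t-test when normal,
    Wilcoxon signed-rank otherwise (exact p for n <= 25, normal
    approximation with continuity correction above). All-zero differences
    short-circuit to statistic 0, p = 1.
    """
    t1 = np.asarray(values_t1, dtype=float)
    t2 = np.asarray(values_t2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError(f"paired vectors differ in length: {t1.size} vs {t2.size}")
    mask = ~(np.isnan(t1) | np.isnan(t2))
    t1, t2 = t1[mask], t2[mask]
    n = t1.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    diffs = t2 - t1
    if np.all(diffs == 0):
        return PairedTestResult("paired-t", 0.0, 1.0, n)
    if _shapiro_normal(diffs):
        res = sps.ttest_rel(t2, t1)
        return PairedTestResult("paired-t", float(res.statistic),
                                float(res.pvalue), n)
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(t2, t1, correction=(method == "approx"), method=method)
    return PairedTestResult("wilcoxon", float(res.statistic),
                            float(res.pvalue), n)


def _screen_one(
    y: np.ndarray, x: pd.Series, spec: CovariateSpec
) -> tuple[str, float] | None:
    """Association test of one candidate against the dependent; returns
    (test name, p) or None when the candidate is untestable."""
    if spec.kind == "continuous":
        xv = np.asarray(x, dtype=float)
        if np.ptp(xv) == 0:
            return None
        if _shapiro_normal(y) and _shapiro_normal(xv):
            return "pearson", float(sps.pearsonr(xv, y).pvalue)
        return "spearman", float(sps.spearmanr(xv, y).pvalue)
    groups = [y[np.asarray(x) == lev] for lev in pd.unique(x)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        return None
    if spec.kind == "binary":
        if all(_shapiro_normal(g) for g in groups[:2]):
            return "t-test", float(sps.ttest_ind(*groups[:2]).pvalue)
        return "mann-whitney", float(
            sps.mannwhitneyu(*groups[:2], alternative="two-sided").pvalue
        )
    if all(_shapiro_normal(g) for g in groups):
        return "anova", float(sps.f_oneway(*groups).pvalue)
    return "kruskal-wallis", float(sps.kruskal(*groups).pvalue)


def screen_covariates(
    cohort: pd.DataFrame,
    dependent: str,
    candidates: list[CovariateSpec],
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Select candidate covariates by p < ``alpha`` association with the
    dependent variable.

    Continuous candidates are screened by correlation (Pearson when both
    variables pass the normality gate, Spearman otherwise), binary ones by
    a two-group comparison, categorical ones by one-way ANOVA or
    Kruskal-Wallis. Candidates with a single observed level are skipped
    with a warning.
    """
    if dependent not in cohort.columns:
        raise ValueError(f"dependent column {dependent!r} not in cohort table")
    results: list[ScreenResult] = []
    for spec in candidates:
        if spec.name not in cohort.columns:
            raise ValueError(f"candidate column {spec.name!r} not in cohort table")
        sub = cohort[[dependent, spec.name]].dropna()
        x = sub[spec.name]
        if x.nunique() < 2:
            warnings.warn(
                f"covariate {spec.name!r} has a single observed level; skipped",
                stacklevel=2,
            )
            continue
        outcome = _screen_one(sub[dependent].to_numpy(dtype=float), x, spec)
        if outcome is None:
            warnings.warn(
                f"covariate {spec.name!r} untestable (degenerate groups); skipped",
                stacklevel=2,
            )
            continue
        test_used, p = outcome
        results.append(
            ScreenResult(spec.name, spec.kind, test_used, p, p < alpha)
        )
    return results


def drop_collinear(
    cohort: pd.DataFrame, candidates: list[str], r_threshold: float = 0.8
) -> list[str]:
    """Resolve pairwise collinearity among continuous candidates.

    When two candidates correlate with \\|r\\| > ``r_threshold``, the one
    listed first is kept and the drop is logged.
    """
    kept: list[str] = []
    for name in candidates:
        clash = None
        for prev in kept:
            sub = cohort[[prev, name]].dropna()
            if len(sub) < 3:
                continue
            r = np.corrcoef(sub[prev], sub[name])[0, 1]
            if np.isfinite(r) and abs(r) > r_threshold:
                clash = (prev, r)
                break
        if clash is None:
            kept.append(name)
        else:
            logger.info(
                "drop_collinear: dropped %r (|r|=%.3f with earlier candidate %r)",
                name, abs(clash[1]), clash[0],
            )
    return kept


def _encode_design(
    predictors: pd.DataFrame, covariate_specs: dict[str, CovariateSpec]
) -> pd.DataFrame:
    """Reference-coded numeric design matrix; categorical columns expand to
    indicator sets (reference level omitted)."""
    cols: dict[str, np.ndarray] = {}
    for name in predictors.columns:
        spec = covariate_specs.get(name)
        col = predictors[name]
        if spec is not None and spec.kind in ("binary", "categorical") and (
            col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
        ):
            levels = sorted(str(v) for v in col.dropna().unique())
            reference = spec.reference if spec.reference is not None else levels[0]
            if str(reference) not in levels:
                raise ValueError(
                    f"covariate {name!r}: reference level {reference!r} not "
                    f"among observed levels {levels}"
                )
            for lev in levels:
                if lev == str(reference):
                    continue
                cols[f"{name}[{lev}]"] = (
                    col.astype(str) == lev
                ).to_numpy(dtype=float)
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=predictors.index)


def backward_regression(
    y,
    predictors: pd.DataFrame,
    covariate_specs: dict[str, CovariateSpec] | None = None,
    removal_threshold: float = DEFAULT_REMOVAL_THRESHOLD,
) -> RegressionResult:
    """Backward-elimination ordinary least squares.

    All entered predictors are fit; while the largest predictor p-value is
    at or above ``removal_threshold``, that predictor is removed and the
    model refit. Categorical predictors enter as reference-coded indicator
    sets and are removed indicator-by-indicator. Betas are standardized on
    the analysis sample (b * sd(x) / sd(y)).

    Raises
    ------
    ValueError
        On exact collinearity (names the dependent columns) or when n is
        too small for the entered design.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=predictors.index,
                  name=getattr(y, "name", None) or "y")
    design = _encode_design(predictors, covariate_specs or {})
    frame = pd.concat([y, design], axis=1).dropna()
    yv = frame.iloc[:, 0]
    design = frame.iloc[:, 1:]
    n = len(frame)
    if n <= design.shape[1] + 1:
        raise ValueError(
            f"n = {n} too small for {design.shape[1]} predictors (need "
            f"n > p + 1)"
        )
    x_full = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        # identify columns dependent on their predecessors via QR pivoting
        dependent_cols = []
        for j in range(1, x_full.shape[1]):
            if np.linalg.matrix_rank(x_full[:, : j + 1]) == np.linalg.matrix_rank(
                x_full[:, :j]
            ):
                dependent_cols.append(design.columns[j - 1])
        raise ValueError(
            f"exact collinearity among predictors; dependent columns: "
            f"{dependent_cols}"
        )

    current = list(design.columns)
    excluded: list[tuple[str, float]] = []
    fit = None
    while True:
        x = sm.add_constant(design[current].to_numpy(dtype=float),
                            has_constant="add") if current else np.ones((n, 1))
        fit = sm.OLS(yv.to_numpy(), x).fit()
        if not current:
            break
        pvals = fit.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] >= removal_threshold:
            excluded.append((current[worst], float(pvals[worst])))
            current.pop(worst)
        else:
            break

    sd_y = yv.std(ddof=1)
    retained = [
        (
            name,
            float(fit.params[k + 1] * design[name].std(ddof=1) / sd_y),
            float(fit.pvalues[k + 1]),
        )
        for k, name in enumerate(current)
    ]
    if current:
        f_stat = float(fit.fvalue)
        model_p = float(fit.f_pvalue)
        df = (int(fit.df_model), int(fit.df_resid))
        adj_r2 = float(fit.rsquared_adj)
    else:  # intercept-only model: no variance explained
        f_stat, model_p, df, adj_r2 = float("nan"), float("nan"), (0, n - 1), 0.0
    return RegressionResult(
        dependent=str(yv.name),
        retained=retained,
        excluded=excluded,
        adj_r2=adj_r2,
        f_stat=f_stat,
        df=df,
        model_p=model_p,
        n=n,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m.

    Summaries report it at 4 decimals (0.05 over three tests prints 0.0167).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m
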