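"""Covariate-adjusted group inference and metric–behavior correlations.

Group differences in every AUC metric are tested with a linear model
``value ~ intercept + group + age + sex + education`` (ANCOVA-equivalent of
a covariate-adjusted two-sample t-test); the group coefficient's t statistic
and two-tailed p are reported, with Cohen's d recovered from t as
``d = |t| * sqrt(1/n1 + 1/n2)``.  A residualize-then-t mode is also
provided.  Multiplicity is controlled per declared family with the
Benjamini–Hochberg step-up FDR.  Brain–behavior relations are partial
correlations of nodal metrics with clinical scores, controlling the same
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "CorrelationResult",
    "InferenceConfig",
    "residualize",
    "adjusted_group_test",
    "cohens_d_from_t",
    "bh_fdr",
    "partial_correlation",
    "run_group_analysis",
]

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class StatResult:
    """Adjusted group test for one metric (optionally one node)."""

    name: str
    t: float
    p: float
    d: float
    n1: int
    n2: int
    df: int
    p_fdr: float = np.nan
    node: str | None = None


@dataclass
class CorrelationResult:
    """Partial correlation between one nodal metric and one clinical score."""

    node: str
    score: str
    r: float
    p: float
    df: int
    n: int
    p_fdr: float = np.nan


@dataclass(frozen=True)
class InferenceConfig:
    """Which covariates to adjust for, test mode, and correlation targets.

    ``mode='ancova'`` fits value ~ group + covariates and tests the group
    coefficient; ``mode='residualize'`` regresses out covariates (pooled)
    and applies a plain two-sample t-test to the residuals.  Correlations
    are computed within the patient group by default (behavioral scores are
    near-floor in controls).
    """

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    mode: Literal["ancova", "residualize"] = "ancova"
    alpha: float = 0.05
    correlation_scores: tuple[str, ...] = ("FBI_apathy", "FBI_disinhibition")
    correlation_metric: str = "efficiency"
    correlation_group: str = "patient"
    #: FDR family for correlations: "per_node" adjusts each node's scores
    #: together (the family size implied by published adjusted p-values);
    #: "all_pairs" pools every node x score test into one family.
    correlation_family: Literal["per_node", "all_pairs"] = "per_node"


def _design(covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(covariates)), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    return X


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``y`` on [intercept, covariates].

    With no covariates this is simple mean-centering.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return y - y.mean()
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != len(y):
        covariates = covariates.T
    X = _design(covariates)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Effect size from a two-sample t statistic: ``|t| sqrt(1/n1 + 1/n2)``."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    return abs(float(t)) * np.sqrt(1.0 / n1 + 1.0 / n2)


def adjusted_group_test(
    values: np.ndarray,
    groups: Sequence[str] | np.ndarray,
    covariates: np.ndarray | None = None,
    mode: Literal["ancova", "residualize"] = "ancova",
    name: str = "",
) -> StatResult:
    """Two-group comparison of a metric, adjusting for covariates.

    The group factor is coded patient = 1, control = 0, so a negative t
    means the metric is lower in patients.  With constant covariates (or
    none) both modes reduce to the classic pooled two-sample t-test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    # patient coded 1 when present; otherwise the lexicographically later label
    pos = "patient" if "patient" in labels else labels[1]
    g = (groups == pos).astype(float)
    n1, n2 = int(g.sum()), int((1 - g).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 subjects")
    if np.ptp(values) == 0:
        raise ValueError(f"metric {name!r} is constant; t undefined")

    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(values):
            cov = cov.T
        # drop constant covariate columns: they are absorbed by the intercept
        cov = cov[:, np.ptp(cov, axis=0) > 0]
    else:
        cov = np.empty((len(values), 0))

    if mode == "ancova":
        X = _design(np.column_stack([g, cov]) if cov.size else g.reshape(-1, 1))
        fit = sm.OLS(values, X).fit()
        t = float(fit.tvalues[1])
        p = float(fit.pvalues[1])
        df = int(fit.df_resid)
    elif mode == "residualize":
        resid = residualize(values, cov if cov.size else None)
        t_, p_ = sps.ttest_ind(resid[g == 1], resid[g == 0], equal_var=True)
        t, p = float(t_), float(p_)
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult(
        name=name, t=t, p=p, d=cohens_d_from_t(t, n1, n2),
        n1=n1, n2=n2, df=df,
    )


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    node: str = "",
    score: str = "",
) -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    r is the correlation of the two covariate-residualized variables;
    df = n - 2 - k and the two-tailed p comes from
    ``t = r sqrt(df / (1 - r^2))``.  With no covariates this is the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = 0
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        k = cov.shape[1]
    else:
        cov = None
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = residualize(x, cov)
    ry = residualize(y, cov)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(node=node, score=score, r=r, p=p, df=df, n=n)


@dataclass
class GroupAnalysisResult:
    """All group tests and correlations, FDR-adjusted per family."""

    global_tests: list[StatResult] = field(default_factory=list)
    nodal_tests: dict[str, list[StatResult]] = field(default_factory=dict)
    correlations: list[CorrelationResult] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)

    def global_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.t, s.p, s.p_fdr, s.d) for s in self.global_tests],
            columns=["metric", "t", "p", "p_fdr", "cohens_d"],
        )

    def nodal_frame(self) -> pd.DataFrame:
        rows = [
            (m, s.node, s.t, s.p, s.p_fdr, s.d)
            for m, tests in self.nodal_tests.items()
            for s in tests
        ]
        return pd.DataFrame(
            rows, columns=["metric", "node", "t", "p", "p_fdr", "cohens_d"]
        )

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.node, c.score, c.r, c.p, c.p_fdr, c.n) for c in self.correlations],
            columns=["node", "score", "r", "p", "p_fdr", "n"],
        )


def _covariate_matrix(meta: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    cols = []
    for name in names:
        col = meta[name]
        if col.dtype == object or str(col.dtype) == "category":
            # binary indicator for the lexicographically later level (e.g. sex M/F -> M=1)
            levels = sorted(col.dropna().unique().tolist())
            if len(levels) > 2:
                raise ValueError(f"covariate {name!r} has more than 2 levels")
            cols.append((col == levels[-1]).astype(float).to_numpy())
        else:
            cols.append(col.astype(float).to_numpy())
    return np.column_stack(cols) if cols else np.empty((len(meta), 0))


def run_group_analysis(
    global_aucs: pd.DataFrame,
    nodal_aucs: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    config: InferenceConfig | None = None,
) -> GroupAnalysisResult:
    """Adjusted tests for every AUC metric plus metric–behavior correlations.

    Parameters
    ----------
    global_aucs
        Subjects x global AUC metrics (columns e.g. aCp, aLp, ...), indexed
        by subject id.
    nodal_aucs
        Per nodal-metric frames of subjects x nodes (AUC values).
    metadata
        Per-subject table with ``group`` plus covariates and clinical
        scores; indexed by subject id, aligned to the metric tables.

    FDR families: all global metrics together (one family); each nodal
    metric across its nodes (one family per metric type); all tested
    node-score correlation pairs (one family).  Subjects missing a score are
    dropped from that correlation and counted in ``dropped``.
    """
    config = config or InferenceConfig()
    meta = metadata.loc[global_aucs.index]
    groups = meta["group"].to_numpy()
    cov = _covariate_matrix(meta, config.covariates)
    out = GroupAnalysisResult()

    tests = [
        adjusted_group_test(
            global_aucs[mcol].to_numpy(), groups, cov, mode=config.mode, name=mcol
        )
        for mcol in global_aucs.columns
    ]
    for s, q in zip(tests, bh_fdr([s.p for s in tests])):
        s.p_fdr = float(q)
    out.global_tests = tests

    for metric, table in nodal_aucs.items():
        table = table.loc[global_aucs.index]
        nodal = []
        for node in table.columns:
            vals = table[node].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.ptp(vals) == 0:
                continue  # undefined (e.g. infinite path length) or constant
            s = adjusted_group_test(vals, groups, cov, mode=config.mode, name=metric)
            s.node = str(node)
            nodal.append(s)
        for s, q in zip(nodal, bh_fdr([s.p for s in nodal])):
            s.p_fdr = float(q)
        out.nodal_tests[metric] = nodal

    # ---- partial correlations (within the configured group) --------------
    corr_metric = config.correlation_metric
    n_covar = cov.shape[1]
    in_grp = meta["group"].to_numpy() == config.correlation_group
    if (
        corr_metric in nodal_aucs
        and len(config.correlation_scores)
        and int(in_grp.sum()) > n_covar + 2
    ):
        table = nodal_aucs[corr_metric].loc[global_aucs.index]
        corrs: list[CorrelationResult] = []
        for score in config.correlation_scores:
            sc = meta.loc[in_grp, score]
            keep = sc.notna().to_numpy()
            n_drop = int((~keep).sum())
            if n_drop:
                out.dropped[score] = n_drop
            y = sc.to_numpy(dtype=float)[keep]
            cov_g = cov[in_grp][keep]
            for node in table.columns:
                x = table.loc[in_grp, node].to_numpy(dtype=float)[keep]
                if not np.all(np.isfinite(x)) or np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                corrs.append(
                    partial_correlation(x, y, cov_g, node=str(node), score=score)
                )
        if config.correlation_family == "per_node":
            by_node: dict[str, list[CorrelationResult]] = {}
            for c in corrs:
                by_node.setdefault(c.node, []).append(c)
            for group_ in by_node.values():
                for c, q in zip(group_, bh_fdr([c.p for c in group_])):
                    c.p_fdr = float(q)
        else:
            for c, q in zip(corrs, bh_fdr([c.p for c in corrs])):
                c.p_fdr = float(q)
        out.correlations = corrs
    return out
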