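"""Nonparametric cohort statistics over pre/post feature tables.

Workflow mirrors a typical paired-imaging analysis: Shapiro-Wilk normality
screening per feature, paired Wilcoxon signed-rank tests of pre- versus
post-therapy values (Z > 0 meaning the feature predominantly decreased
after therapy), Spearman rank correlation of every pre- and post-feature
against clinical covariates with conventional strength bands on |rho|
(low < 0.3 <= moderate < 0.5 <= strong < 0.7 <= very strong < 0.9 <= full),
and Mann-Whitney U comparison of features between two outcome groups.

No multiple-testing correction is applied to the primary p-values; a
Benjamini-Hochberg column is emitted alongside them as a clearly labeled
extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, DegenerateInputError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "AnalysisReport",
    "StatsConfig",
    "normality_test",
    "wilcoxon_paired",
    "spearman",
    "classify_strength",
    "mann_whitney",
    "run_cohort_analysis",
    "cohort_summary",
]

log = logging.getLogger(__name__)

FIGO_ORDER = {"IIIC1": 1, "IIIC2": 2, "IVB": 3}
RECURRENCE_ORDER = {"none": 0, "local": 1, "distant": 2}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    band: str
    sign: str


def normality_test(values) -> TestResult:
    """Shapiro-Wilk test of normality."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 3:
        raise DegenerateInputError(f"Shapiro-Wilk requires n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(p), int(x.size), "shapiro-wilk")


def wilcoxon_paired(pre, post, zero_method: str = "wilcox") -> TestResult:
    """Paired Wilcoxon signed-rank test with normal approximation.

    The statistic is the signed Z: positive when pre > post predominates
    (i.e. the feature decreased after therapy).  Zero differences are
    discarded by default (``"wilcox"``); ``"pratt"`` keeps them in the
    ranking.  All-zero differences are degenerate (p = 1, n_effective = 0),
    not an error.
    """
    pre = np.asarray(pre, dtype=np.float64).ravel()
    post = np.asarray(post, dtype=np.float64).ravel()
    if pre.size != post.size:
        raise DataError("pre and post must be paired vectors of equal length")
    d = pre - post
    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon-signed-rank", degenerate=True)
    if n_eff < 5:
        raise DegenerateInputError(
            f"Wilcoxon requires >= 5 nonzero differences, got {n_eff}"
        )
    if zero_method not in ("wilcox", "pratt"):
        raise ConfigError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        dd = d[nonzero]
        ranks = sps.rankdata(np.abs(dd))
        w_plus = float(ranks[dd > 0].sum())
        n = n_eff
        mu = n * (n + 1) / 4.0
        # tie correction on the rank variance
        _, t = np.unique(np.abs(dd), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((t**3 - t).sum()) / 48.0
    else:
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        # Pratt: zeros ranked but dropped from the statistic
        n = d.size
        n0 = n - n_eff
        mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
        _, t = np.unique(np.abs(d[nonzero]), return_counts=True)
        var = (
            n * (n + 1) * (2 * n + 1) / 24.0
            - n0 * (n0 + 1) * (2 * n0 + 1) / 24.0
            - ((t**3 - t).sum()) / 48.0
        )
    if var <= 0:
        return TestResult(0.0, 1.0, n_eff, "wilcoxon-signed-rank", degenerate=True)
    z = (w_plus - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), n_eff, "wilcoxon-signed-rank")


def classify_strength(rho: float) -> str:
    """Band a correlation coefficient by |rho| on the conventional cut-offs."""
    if not np.isfinite(rho) or abs(rho) > 1:
        raise DataError(f"correlation must lie in [-1, 1], got {rho}")
    a = abs(rho)
    if a == 0:
        return "none"
    if a < 0.3:
        return "low"
    if a < 0.5:
        return "moderate"
    if a < 0.7:
        return "strong"
    if a < 0.9:
        return "very strong"
    return "full"  # includes |rho| = 1 by documented extension


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and t-approximation p."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 4:
        raise DegenerateInputError(f"Spearman requires n >= 4, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Spearman undefined when a variable is constant")
    rho, p = sps.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    sign = "+" if rho > 0 else ("-" if rho < 0 else "0")
    return CorrelationResult(rho, float(p), int(x.size), classify_strength(rho), sign)


def mann_whitney(group_a, group_b) -> TestResult:
    """Mann-Whitney U with tie-corrected normal-approximation two-sided p."""
    a = np.asarray(group_a, dtype=np.float64).ravel()
    b = np.asarray(group_b, dtype=np.float64).ravel()
    if a.size < 3 or b.size < 3:
        raise DegenerateInputError(
            f"Mann-Whitney requires n >= 3 per group, got {a.size} and {b.size}"
        )
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(u), float(p), int(a.size + b.size), "mann-whitney-u")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (extension column)."""
    p = np.asarray(p, dtype=np.float64)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if ok.sum() == 0:
        return out
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0, 1)
    out[ok] = adj
    return out


@dataclass
class StatsConfig:
    """Knobs of the cohort analysis left open by convention.

    ``recurrence_coding``: ``"binary"`` (any recurrence vs none, the primary
    analysis) or ``"ordinal"`` (none < local < distant).
    ``group_variable``: clinical column defining the two-group Mann-Whitney
    comparison (binary-codable).
    """

    alpha: float = 0.05
    recurrence_coding: str = "binary"
    group_variable: str = "recurrence"
    zero_method: str = "wilcox"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.recurrence_coding not in ("binary", "ordinal"):
            raise ConfigError(f"unknown recurrence coding {self.recurrence_coding!r}")


@dataclass
class AnalysisReport:
    """Tabular output of :func:`run_cohort_analysis`."""

    normality: pd.DataFrame
    paired_change: pd.DataFrame
    correlations: pd.DataFrame
    group_comparison: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_dir(self, out_dir) -> None:
        """Write the CSV tables, a JSON mirror, and a markdown summary."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        self.normality.to_csv(out / "normality.csv", index=False, float_format=fmt)
        self.paired_change.to_csv(
            out / "paired_change.csv", index=False, float_format=fmt
        )
        self.correlations.to_csv(
            out / "correlations.csv", index=False, float_format=fmt
        )
        self.group_comparison.to_csv(
            out / "group_comparison.csv", index=False, float_format=fmt
        )
        mirror = {
            "meta": self.meta,
            "normality": self.normality.to_dict(orient="records"),
            "paired_change": self.paired_change.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "group_comparison": self.group_comparison.to_dict(orient="records"),
        }
        (out / "report.json").write_text(json.dumps(mirror, indent=2, default=str))
        (out / "summary.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        alpha = self.meta.get("alpha", 0.05)
        lines = [
            "# Cohort analysis summary",
            "",
            f"alpha = {alpha} (configurable); p-values below 0.001 are shown as <0.001.",
            f"Patients with both timepoints: {self.meta.get('n_pairs', '?')}"
            f" (excluded incomplete: {self.meta.get('n_excluded', 0)})",
            "",
            "## Significant paired pre/post changes (Wilcoxon)",
        ]
        sig = self.paired_change[self.paired_change["p_value"] < alpha]
        for _, r in sig.iterrows():
            p = "<0.001" if r["p_value"] < 1e-3 else f"{r['p_value']:.4g}"
            lines.append(
                f"- {r['feature']}: Z = {r['z']:.3g} ({r['direction']}), p = {p}"
            )
        lines.append("")
        lines.append("## Significant feature-covariate Spearman correlations")
        sig = self.correlations[self.correlations["p_value"] < alpha]
        for _, r in sig.iterrows():
            p = "<0.001" if r["p_value"] < 1e-3 else f"{r['p_value']:.4g}"
            lines.append(
                f"- {r['feature']} x {r['covariate']}: R = {r['rho']:+.3g}"
                f" ({r['band']}), p = {p}"
            )
        lines.append("")
        return "\n".join(lines)


def _encode_covariates(clinical: pd.DataFrame, coding: str) -> pd.DataFrame:
    cov = pd.DataFrame(index=clinical.index)
    cov["age"] = pd.to_numeric(clinical["age"])
    cov["figo"] = clinical["figo"].map(FIGO_ORDER)
    cov["response"] = (clinical["response"] == "responder").astype(int)
    if coding == "binary":
        cov["recurrence"] = (clinical["recurrence"] != "none").astype(int)
    else:
        cov["recurrence"] = clinical["recurrence"].map(RECURRENCE_ORDER)
    return cov


def run_cohort_analysis(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    config: StatsConfig | None = None,
) -> AnalysisReport:
    """Full statistical pass over a paired feature table and clinical covariates.

    ``features`` must hold one row per (patient_id, timepoint in {pre, post})
    with numeric feature columns.  Patients missing a timepoint are excluded
    (with a logged count); fewer than 5 complete pairs is an error.  The
    analysis itself is deterministic.
    """
    config = config or StatsConfig()
    if "patient_id" not in features.columns or "timepoint" not in features.columns:
        raise DataError("feature table needs patient_id and timepoint columns")
    known = set(clinical["patient_id"])
    orphan = set(features["patient_id"]) - known
    if orphan:
        raise DataError(f"feature rows without clinical match: {sorted(orphan)[:5]}")

    meta_cols = {"patient_id", "timepoint", "glcm_levels", "glcm_mode"}
    feat_cols = [
        c
        for c in features.columns
        if c not in meta_cols and pd.api.types.is_numeric_dtype(features[c])
    ]
    wide = features.pivot(index="patient_id", columns="timepoint", values=feat_cols)
    # a patient is complete when both timepoints exist
    has_pre = features[features.timepoint == "pre"].patient_id
    has_post = features[features.timepoint == "post"].patient_id
    paired_ids = sorted(set(has_pre) & set(has_post))
    n_excluded = len(set(features.patient_id) - set(paired_ids))
    if n_excluded:
        log.warning("excluded %d patients missing a timepoint", n_excluded)
    if len(paired_ids) < 5:
        raise DataError(f"fewer than 5 complete pre/post pairs ({len(paired_ids)})")
    wide = wide.loc[paired_ids]
    clin = clinical.set_index("patient_id").loc[paired_ids]
    cov = _encode_covariates(clin.reset_index(), config.recurrence_coding)
    cov.index = clin.index

    # 1) normality screening per feature and timepoint
    norm_rows = []
    for f in feat_cols:
        for tp in ("pre", "post"):
            x = wide[(f, tp)].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            try:
                r = normality_test(x)
                norm_rows.append(
                    dict(feature=f, timepoint=tp, w=r.statistic, p_value=r.p_value,
                         n=r.n_effective, normal=r.p_value >= config.alpha)
                )
            except DegenerateInputError as exc:
                norm_rows.append(
                    dict(feature=f, timepoint=tp, w=np.nan, p_value=np.nan,
                         n=len(x), normal=np.nan, note=str(exc))
                )
    normality = pd.DataFrame(norm_rows)

    # 2) paired pre vs post Wilcoxon per feature
    paired_rows = []
    for f in feat_cols:
        pre = wide[(f, "pre")].to_numpy(dtype=float)
        post = wide[(f, "post")].to_numpy(dtype=float)
        ok = np.isfinite(pre) & np.isfinite(post)
        try:
            r = wilcoxon_paired(pre[ok], post[ok], zero_method=config.zero_method)
            direction = (
                "decrease" if r.statistic > 0 else
                ("increase" if r.statistic < 0 else "none")
            )
            paired_rows.append(
                dict(feature=f, z=r.statistic, p_value=r.p_value,
                     n_effective=r.n_effective, direction=direction,
                     degenerate=r.degenerate)
            )
        except DegenerateInputError as exc:
            paired_rows.append(
                dict(feature=f, z=np.nan, p_value=np.nan, n_effective=int(ok.sum()),
                     direction="undefined", degenerate=True, note=str(exc))
            )
    paired = pd.DataFrame(paired_rows)
    paired["p_bh_extension"] = _bh_adjust(paired["p_value"].to_numpy())

    # 3) Spearman of every pre-/post-feature against each covariate
    corr_rows = []
    for f in feat_cols:
        for tp in ("pre", "post"):
            x = wide[(f, tp)].to_numpy(dtype=float)
            for cname in ("age", "figo", "response", "recurrence"):
                y = cov[cname].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                row = dict(feature=f"{tp}_{f}", covariate=cname)
                try:
                    r = spearman(x[ok], y[ok])
                    row.update(rho=r.rho, p_value=r.p_value, n=r.n,
                               band=r.band, sign=r.sign)
                except DegenerateInputError as exc:
                    row.update(rho=np.nan, p_value=np.nan, n=int(ok.sum()),
                               band="undefined", sign="", note=str(exc))
                corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)
    correlations["p_bh_extension"] = _bh_adjust(correlations["p_value"].to_numpy())

    # 4) Mann-Whitney between outcome groups
    gvar = config.group_variable
    if gvar == "recurrence":
        groups = (clin["recurrence"] != "none").astype(int)
        group_labels = ("no-recurrence", "any-recurrence")
    elif gvar == "response":
        groups = (clin["response"] == "responder").astype(int)
        group_labels = ("non-responder", "responder")
    else:
        raise ConfigError(f"unsupported group variable {gvar!r}")
    grp_rows = []
    for f in feat_cols:
        for tp in ("pre", "post"):
            x = wide[(f, tp)].to_numpy(dtype=float)
            a = x[(groups == 0).to_numpy() & np.isfinite(x)]
            b = x[(groups == 1).to_numpy() & np.isfinite(x)]
            row = dict(feature=f"{tp}_{f}", group_a=group_labels[0],
                       group_b=group_labels[1], n_a=len(a), n_b=len(b))
            try:
                r = mann_whitney(a, b)
                row.update(u=r.statistic, p_value=r.p_value)
            except DegenerateInputError as exc:
                row.update(u=np.nan, p_value=np.nan, note=str(exc))
            grp_rows.append(row)
    group_comparison = pd.DataFrame(grp_rows)
    group_comparison["p_bh_extension"] = _bh_adjust(
        group_comparison["p_value"].to_numpy()
    )

    meta = dict(
        alpha=config.alpha,
        recurrence_coding=config.recurrence_coding,
        group_variable=gvar,
        n_pairs=len(paired_ids),
        n_excluded=n_excluded,
    )
    return AnalysisReport(normality, paired, correlations, group_comparison, meta)


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Counts and rounded percentages per categorical level; median and range
    for numeric columns.  Mirrors a standard patients-characteristics table."""
    if clinical is None or len(clinical) == 0:
        raise DataError("cohort summary requires a non-empty table")
    n = len(clinical)
    rows = [dict(variable="n", level="", count=n, percent=100, median=np.nan,
                 min=np.nan, max=np.nan)]
    for col in clinical.columns:
        if col == "patient_id":
            continue
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series):
            rows.append(
                dict(variable=col, level="", count=n, percent=np.nan,
                     median=float(series.median()), min=float(series.min()),
                     max=float(series.max()))
            )
        else:
            counts = series.value_counts()
            for level, c in counts.items():
                rows.append(
                    dict(variable=col, level=str(level), count=int(c),
                         percent=int(round(100.0 * c / n)), median=np.nan,
                         min=np.nan, max=np.nan)
                )
    return pd.DataFrame(rows)
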