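"""Quadrat-count statistics for sea-pen field surveys.

A survey counts animals in a systematic grid of quadrats (the field
protocol used thirty 4 m² quadrats per pen), recording surface and buried
individuals separately.  Aggregation is screened with the dispersion
index: for quadrat counts with sample mean ``Mean`` and sample variance
``Var`` (n-1 denominator),

    t = (Var/Mean - 1) / sqrt(2 / (n - 1))

is approximately Student-t with n-1 degrees of freedom under a Poisson
(random) null; large positive t indicates overdispersion, i.e. clumping.
The module also provides the survey-level comparisons used alongside it:
a two-way ANOVA without replication across pens and months, and a paired
t-test between surface and buried layer means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LAYERS = ("surface", "buried", "combined")


@dataclass(frozen=True)
class QuadratSurvey:
    """One survey: per-quadrat counts for both layers of one pen-month."""

    pen_id: str
    month: str
    counts_surface: np.ndarray
    counts_buried: np.ndarray
    quadrat_area: float = 4.0  # m^2

    def __post_init__(self) -> None:
        s = np.asarray(self.counts_surface, dtype=int)
        b = np.asarray(self.counts_buried, dtype=int)
        if s.shape != b.shape:
            raise ValueError(
                f"surface and buried grids differ in shape: {s.shape} vs {b.shape}"
            )
        if s.size < 2:
            raise ValueError("a survey needs at least 2 quadrats")
        if (s < 0).any() or (b < 0).any():
            raise ValueError("quadrat counts must be non-negative")
        if not self.quadrat_area > 0:
            raise ValueError("quadrat_area must be positive")
        object.__setattr__(self, "counts_surface", s)
        object.__setattr__(self, "counts_buried", b)

    def layer(self, which: str) -> np.ndarray:
        if which == "surface":
            return self.counts_surface
        if which == "buried":
            return self.counts_buried
        if which == "combined":
            return self.counts_surface + self.counts_buried
        raise ValueError(f"unknown layer {which!r}; expected one of {LAYERS}")


@dataclass(frozen=True)
class DispersionTestResult:
    n: int
    mean: float
    variance: float
    ratio: float
    t_stat: float
    df: int
    p_value: float
    alpha: float
    significant: bool


@dataclass(frozen=True)
class SurveyBatchSummary:
    layer: str
    n_surveys: int
    n_significant: int
    fraction_significant: float
    results: tuple
    excluded: tuple  # (index, reason) pairs, never silently dropped


def dispersion_test(counts, alpha: float = 0.025) -> DispersionTestResult:
    """One-sided overdispersion test on a grid (or vector) of counts.

    The default alpha of 0.025 flags t above the 0.975 quantile of
    t(n-1), the convention used when only overdispersion is of interest.
    """
    c = np.asarray(counts, dtype=float).ravel()
    n = c.size
    if n < 2:
        raise ValueError(f"dispersion test needs at least 2 quadrats, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mean = float(c.mean())
    if mean == 0:
        raise ValueError(
            "dispersion index undefined: no animals recorded (mean count is 0)"
        )
    var = float(c.var(ddof=1))
    ratio = var / mean
    t = (ratio - 1.0) / np.sqrt(2.0 / (n - 1))
    p = float(stats.t.sf(t, df=n - 1))
    return DispersionTestResult(
        n=n, mean=mean, variance=var, ratio=ratio, t_stat=float(t),
        df=n - 1, p_value=p, alpha=alpha, significant=p < alpha,
    )


def survey_batch(
    surveys, layer: str = "combined", alpha: float = 0.025
) -> SurveyBatchSummary:
    """Dispersion test per survey for one layer, with counts of rejections.

    Surveys on which the test is undefined (e.g. an empty layer) are
    excluded with a logged reason and reported in ``excluded``.
    """
    surveys = list(surveys)
    if not surveys:
        raise ValueError("survey_batch needs at least one survey")
    results, excluded = [], []
    for i, sv in enumerate(surveys):
        try:
            results.append(dispersion_test(sv.layer(layer), alpha=alpha))
        except ValueError as exc:
            log.warning("survey %d (%s %s) excluded: %s", i, sv.pen_id, sv.month, exc)
            excluded.append((i, str(exc)))
    n_sig = sum(r.significant for r in results)
    n_tested = len(results)
    return SurveyBatchSummary(
        layer=layer,
        n_surveys=len(surveys),
        n_significant=n_sig,
        fraction_significant=n_sig / n_tested if n_tested else float("nan"),
        results=tuple(results),
        excluded=tuple(excluded),
    )


def batch_table(surveys, alpha: float = 0.025) -> pd.DataFrame:
    """Three-row summary (buried / surface / combined) across all surveys."""
    rows = []
    for layer in ("buried", "surface", "combined"):
        s = survey_batch(surveys, layer=layer, alpha=alpha)
        rows.append(
            {
                "layer": layer,
                "n_surveys": s.n_surveys,
                "n_significant": s.n_significant,
                "pct_significant": round(100.0 * s.fraction_significant),
            }
        )
    return pd.DataFrame(rows)


def density_summary(surveys):
    """Per-quadrat and per-m² density summaries over combined layers.

    Returns (mean_per_quadrat, mean_per_m2, occupancy_fraction, max_count).
    """
    surveys = list(surveys)
    if not surveys:
        raise ValueError("density_summary needs at least one survey")
    counts = np.concatenate([sv.layer("combined").ravel() for sv in surveys])
    areas = np.concatenate(
        [np.full(sv.layer("combined").size, sv.quadrat_area) for sv in surveys]
    )
    mean_q = float(counts.mean())
    mean_m2 = float((counts / areas).mean())
    occupancy = float((counts > 0).mean())
    return mean_q, mean_m2, occupancy, int(counts.max())


@dataclass(frozen=True)
class AnovaResult:
    f_row: float
    p_row: float
    f_col: float
    p_col: float
    ss_row: float
    ss_col: float
    ss_resid: float
    ss_total: float
    df_row: int
    df_col: int
    df_resid: int


def anova_two_way_no_rep(response) -> AnovaResult:
    """Two-way ANOVA without replication on a complete pens x months matrix.

    Classical decomposition: SS_total = SS_row + SS_col + SS_resid, with
    F_row = MS_row / MS_resid on (a-1, (a-1)(b-1)) df and analogously for
    columns.  A response matrix that is exactly additive leaves zero
    residual SS, making F undefined — that is reported as an error rather
    than an infinite statistic.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("response must be a matrix with at least 2 rows and 2 columns")
    if np.isnan(y).any():
        raise ValueError("response matrix has missing cells; the design must be complete")
    a, b = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_row = b * float(((row_means - grand) ** 2).sum())
    ss_col = a * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_row - ss_col
    df_row, df_col = a - 1, b - 1
    df_resid = df_row * df_col
    if ss_resid <= 1e-12 * max(ss_total, 1.0):
        raise ValueError(
            "degenerate fit: residual sum of squares is zero (additive matrix); "
            "F statistics are undefined"
        )
    ms_resid = ss_resid / df_resid
    f_row = (ss_row / df_row) / ms_resid
    f_col = (ss_col / df_col) / ms_resid
    p_row = float(stats.f.sf(f_row, df_row, df_resid))
    p_col = float(stats.f.sf(f_col, df_col, df_resid))
    return AnovaResult(
        f_row=float(f_row), p_row=p_row, f_col=float(f_col), p_col=p_col,
        ss_row=ss_row, ss_col=ss_col, ss_resid=ss_resid, ss_total=ss_total,
        df_row=df_row, df_col=df_col, df_resid=df_resid,
    )


def paired_t(surface_means, buried_means):
    """Two-sided paired t-test between per-pen surface and buried means.

    Returns (t, df, p_two_sided).
    """
    x = np.asarray(surface_means, dtype=float)
    y = np.asarray(buried_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical vectors: no evidence of any difference
            return 0.0, x.size - 1, 1.0
        raise ValueError("differences have zero variance; the t statistic is undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)
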