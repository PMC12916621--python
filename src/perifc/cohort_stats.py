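"""Group-level statistics for the connectivity metric and clinical outcomes.

The cohort analysis mirrors a small-sample clinical design: split subjects at
the median observed survival time (still-living subjects go to the
long-survival group), screen each group's metric with a one-sample
Kolmogorov-Smirnov test, compare groups with a two-tailed Mann-Whitney U test
(exact by full enumeration at these sample sizes), quantify the effect with
pooled-SD Cohen's d, relate the metric to 6-month Karnofsky Performance
Status (KPS) change with Spearman's rho, and fit an ordinary least-squares
model ``KPS change ~ 1 + metric + age + sex + WHO grade + tumor volume``.

Exactness matters at n = 12, so the Mann-Whitney and Spearman p-values are
computed by enumeration below the sizes where that is feasible; the
large-sample approximations used beyond are the standard tie-corrected normal
and t approximations.  No survival-time model (Kaplan-Meier, Cox) is fit:
group membership itself is the survival summary.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class StatsError(Exception):
    """Base class for statistics failures."""


class DegenerateGroupError(StatsError):
    """A grouping or variance requirement cannot be met."""


VALID_KPS = set(range(0, 101, 10))
WHO_GRADE_NUMERIC = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class SubjectRecord:
    """Clinical covariates, outcomes and the connectivity metric for one subject."""

    id: str
    age_years: float
    sex: str                      # "male" | "female"
    who_grade: str                # "I" | "II" | "III" | "IV"
    tumor_volume_ml: float
    survival_months: float
    alive: bool
    kps_pre: int
    kps_6mo: int | None
    subject_metric: float = float("nan")

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.who_grade not in WHO_GRADE_NUMERIC:
            raise ValueError(f"who_grade must be I-IV, got {self.who_grade!r}")
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")
        if self.kps_pre not in VALID_KPS:
            raise ValueError(f"kps_pre must be a multiple of 10 in 0..100, got {self.kps_pre}")
        if self.kps_6mo is not None and self.kps_6mo not in VALID_KPS:
            raise ValueError(f"kps_6mo must be a multiple of 10 in 0..100, got {self.kps_6mo}")


def kps_change(record: SubjectRecord) -> int | None:
    """6-month KPS minus preoperative KPS.

    A subject deceased before the 6-month follow-up scores 0 at follow-up, so
    the change is ``-kps_pre``.  A living subject with no 6-month score is
    excluded from KPS analyses (returns None).
    """
    if (not record.alive) and record.survival_months < 6:
        return 0 - record.kps_pre
    if record.kps_6mo is None:
        return None
    return record.kps_6mo - record.kps_pre


class SurvivalSplit(NamedTuple):
    short: list[SubjectRecord]
    long: list[SubjectRecord]
    median_months: float


def split_by_median_survival(records: Sequence[SubjectRecord]) -> SurvivalSplit:
    """Median split on observed survival months.

    Living subjects' recorded elapsed months enter the median, and living
    subjects always belong to the long-survival group: short means
    ``survival < median and deceased``.
    """
    if len(records) < 4:
        raise DegenerateGroupError("need at least 4 records for a median split")
    surv = np.asarray([r.survival_months for r in records], dtype=float)
    median = float(np.median(surv))
    short = [r for r in records if (r.survival_months < median) and not r.alive]
    long_ = [r for r in records if (r.survival_months >= median) or r.alive]
    if len(short) < 2 or len(long_) < 2:
        raise DegenerateGroupError(
            f"median split produced groups of sizes {len(short)}/{len(long_)}"
        )
    return SurvivalSplit(short=short, long=long_, median_months=median)


def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS p-value against a normal with the sample mean and SD.

    The textbook test with estimated parameters; no Lilliefors correction.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DegenerateGroupError("KS normality screen needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateGroupError("zero variance: KS test undefined")
    return float(sps.kstest(v, "norm", args=(v.mean(), sd)).pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum U for group a, with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact by full enumeration of all C(n_a + n_b, n_a) group assignments when
    n_a + n_b <= 14 (ties handled through midranks); otherwise the normal
    approximation with tie correction and continuity correction.
    Returns ``(U, p_two_tailed)`` with U oriented to group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    if n < 2 or m < 2:
        raise DegenerateGroupError("each group needs at least 2 values")
    u_obs = _u_statistic(a, b)
    if n + m <= 14:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        us = np.array([
            ranks[list(comb)].sum() - offset
            for comb in itertools.combinations(range(n + m), n)
        ])
        tol = 1e-9
        p_le = float(np.mean(us <= u_obs + tol))
        p_ge = float(np.mean(us >= u_obs - tol))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    nm = n + m
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (nm * (nm - 1.0))
    sigma2 = n * m / 12.0 * (nm + 1.0 - tie_term)
    if sigma2 <= 0:
        raise DegenerateGroupError("all values tied: U test undefined")
    sigma = math.sqrt(sigma2)
    z = (abs(u_obs - mu) - 0.5) / sigma
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return u_obs, p


def cohen_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled-SD Cohen's d, (mean(a) - mean(b)) / s_pooled, sample variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateGroupError("each group needs at least 2 values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise DegenerateGroupError("zero pooled SD: Cohen's d undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho (Pearson correlation of midranks) with a two-tailed p.

    Exact p by full permutation enumeration for n <= 8, else the
    t-approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; filter first")
    n = x.size
    if n < 3:
        raise DegenerateGroupError("Spearman needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateGroupError("zero rank variance")

    def _corr(u: np.ndarray, v: np.ndarray) -> float:
        uc = u - u.mean()
        vc = v - v.mean()
        return float(uc @ vc / (np.linalg.norm(uc) * np.linalg.norm(vc)))

    rho = _corr(rx, ry)
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_corr(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    r = min(abs(rho), 1.0 - 1e-15)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = min(1.0, 2.0 * float(sps.t.sf(t, df=n - 2)))
    return rho, p


@dataclass
class OutcomeModelResult:
    """OLS fit of KPS change on the metric and clinical covariates."""

    table: pd.DataFrame          # coef, ci_low, ci_high, p per term
    f_pvalue: float
    r_squared: float
    r_squared_adj: float
    n: int
    dropped_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "terms": self.table.reset_index().rename(columns={"index": "term"}).to_dict("records"),
            "f_pvalue": self.f_pvalue,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "n": self.n,
            "dropped_terms": self.dropped_terms,
        }


def fit_outcome_model(records: Sequence[SubjectRecord]) -> OutcomeModelResult:
    """OLS: KPS change ~ 1 + metric + age + sex + WHO grade + tumor volume.

    Sex is coded female = 0 / male = 1 and WHO grade enters as a numeric 1-4
    score.  Subjects without a KPS change (no follow-up, still alive) are
    dropped as incomplete cases.  Covariates that are constant in the fitted
    subset (e.g. grade in a single-grade subgroup) are dropped with a warning.
    """
    rows = []
    for r in records:
        dk = kps_change(r)
        if dk is None:
            continue
        rows.append(
            {
                "kps_change": float(dk),
                "connectivity": r.subject_metric,
                "age": r.age_years,
                "sex_male": 1.0 if r.sex == "male" else 0.0,
                "who_grade": float(WHO_GRADE_NUMERIC[r.who_grade]),
                "tumor_volume_ml": r.tumor_volume_ml,
            }
        )
    df = pd.DataFrame(rows)
    predictors = ["connectivity", "age", "sex_male", "who_grade", "tumor_volume_ml"]
    dropped = [c for c in predictors if len(df) and df[c].nunique() <= 1]
    for c in dropped:
        warnings.warn(f"dropping constant predictor {c!r} from the outcome model")
    kept = [c for c in predictors if c not in dropped]
    if len(df) < len(kept) + 2:
        raise DegenerateGroupError(
            f"{len(df)} complete cases cannot support {len(kept)} predictors"
        )
    X = sm.add_constant(df[kept])
    fit = sm.OLS(df["kps_change"], X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return OutcomeModelResult(
        table=table,
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
        dropped_terms=dropped,
    )


@dataclass
class GroupComparison:
    """Survival-group comparison of the connectivity metric."""

    metrics_short: list[float]
    metrics_long: list[float]
    median_months: float
    u_stat: float
    p_two_tailed: float
    cohens_d: float
    ks_p_short: float | None
    ks_p_long: float | None

    def to_dict(self) -> dict:
        return {
            "n_short": len(self.metrics_short),
            "n_long": len(self.metrics_long),
            "median_months": self.median_months,
            "mean_metric_short": float(np.mean(self.metrics_short)),
            "sd_metric_short": float(np.std(self.metrics_short, ddof=1)),
            "mean_metric_long": float(np.mean(self.metrics_long)),
            "sd_metric_long": float(np.std(self.metrics_long, ddof=1)),
            "u_stat": self.u_stat,
            "p_two_tailed": self.p_two_tailed,
            "cohens_d": self.cohens_d,
            "ks_p_short": self.ks_p_short,
            "ks_p_long": self.ks_p_long,
        }


def compare_survival_groups(records: Sequence[SubjectRecord]) -> GroupComparison:
    """Median-survival split plus KS screen, Mann-Whitney U and Cohen's d."""
    split = split_by_median_survival(records)
    ms = [r.subject_metric for r in split.short]
    ml = [r.subject_metric for r in split.long]

    def _ks(vals):
        try:
            return ks_normality(vals)
        except DegenerateGroupError:
            return None

    u, p = mann_whitney_u(ms, ml)
    return GroupComparison(
        metrics_short=ms,
        metrics_long=ml,
        median_months=split.median_months,
        u_stat=u,
        p_two_tailed=p,
        cohens_d=cohen_d(ms, ml),
        ks_p_short=_ks(ms),
        ks_p_long=_ks(ml),
    )
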