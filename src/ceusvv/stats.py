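"""Statistical layer: t tests, one-way ANOVA, Friedman test, Dunnett T3,
Pearson correlation, and the cohort comparison report.

All statistics are computed from their defining formulas (sums of squares,
within-block midranks, Welch–Satterthwaite degrees of freedom) with
p-values taken from the reference distributions in :mod:`scipy.stats`.
Dunnett's T3 adjusts pairwise Welch statistics against the studentized
maximum modulus (SMM) distribution with ``m = k(k-1)/2`` parameters,
evaluated by quadrature over the chi distribution, with a seeded
Monte-Carlo fallback.  Two-sided tests throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "GroupSummary",
    "TestResult",
    "CorrelationResult",
    "PairwiseResult",
    "CohortReport",
    "t_test",
    "one_way_anova",
    "friedman_test",
    "smm_sf",
    "smm_sf_mc",
    "dunnett_t3",
    "pearson_correlation",
    "group_comparison_report",
]

#: fixed seed of the Monte-Carlo SMM fallback
SMM_MC_SEED = 20170801


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: n, mean, sample SD (n-1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("group needs n >= 2")
        if self.sd < 0:
            raise InvalidParameterError("sd must be >= 0")

    @classmethod
    def from_sample(cls, label: str, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise InvalidParameterError("sample needs n >= 2")
        return cls(label=label, n=int(x.size), mean=float(x.mean()),
                   sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: float
    p_value: float
    comparison: tuple[str, ...] = ()
    note: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_value: float

    def fisher_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Classical Fisher z confidence interval (bivariate-normal theory).

        Under-covers when the data are far from bivariate normal; see the
        coverage study in :mod:`ceusvv.studies` for a bootstrap alternative.
        """
        if self.n < 4 or abs(self.r) == 1.0:
            raise InvalidParameterError("Fisher interval needs n >= 4 and |r| < 1")
        z = np.arctanh(self.r)
        half = sps.norm.ppf(0.5 + level / 2.0) / np.sqrt(self.n - 3)
        return float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunnett-T3 pairwise comparison."""

    group_a: str
    group_b: str
    mean_difference: float
    statistic: float
    df: float
    p_adjusted: float
    p_unadjusted: float


def _as_summary(x, label: str) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_sample(label, x)


def _welch_terms(a: GroupSummary, b: GroupSummary):
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        return 0.0, float(a.n + b.n - 2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return se2, df


def t_test(a, b, variant: str = "student") -> TestResult:
    """Two-sample two-sided t test from raw samples or group summaries.

    ``variant="student"`` pools variances with ``df = n_a + n_b - 2``;
    ``variant="welch"`` uses the separate-variance statistic with
    Welch–Satterthwaite df.  Raw inputs are reduced to (n, mean, sd) first,
    so raw and summary inputs give identical results.  When both variances
    are zero the test degenerates: p = 1 for equal means, p = 0 (flagged)
    otherwise.
    """
    A, B = _as_summary(a, "a"), _as_summary(b, "b")
    diff = A.mean - B.mean
    note = None
    if variant == "student":
        df = float(A.n + B.n - 2)
        sp2 = ((A.n - 1) * A.sd**2 + (B.n - 1) * B.sd**2) / df
        se2 = sp2 * (1.0 / A.n + 1.0 / B.n)
    elif variant == "welch":
        se2, df = _welch_terms(A, B)
    else:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    if se2 == 0:
        if diff == 0:
            stat, p = 0.0, 1.0
        else:
            stat = float(np.inf) if diff > 0 else float(-np.inf)
            p, note = 0.0, "degenerate: zero variance with unequal means"
    else:
        stat = diff / np.sqrt(se2)
        p = 2.0 * sps.t.sf(abs(stat), df)
    return TestResult(
        test_name=f"t_{variant}",
        statistic=float(stat),
        df=df,
        p_value=float(min(p, 1.0)),
        comparison=(A.label, B.label),
        note=note,
    )


def one_way_anova(groups: Sequence) -> TestResult:
    """Classical one-way fixed-effects ANOVA on independent samples.

    ``F = MS_between / MS_within`` with (k-1, N-k) df.  When the within
    mean square is zero: F = 0, p = 1 if the between mean square is also
    zero, otherwise an infinite-F degenerate result with p = 0.
    """
    data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2 or any(g.size < 2 for g in data):
        raise InvalidParameterError("need >= 2 groups with n >= 2 each")
    k = len(data)
    ns = np.array([g.size for g in data])
    N = int(ns.sum())
    means = np.array([g.mean() for g in data])
    grand = float(np.concatenate(data).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(data, means)))
    df1, df2 = float(k - 1), float(N - k)
    msb, msw = ssb / df1, ssw / df2
    note = None
    if msw == 0:
        if msb <= 0:
            stat, p = 0.0, 1.0
        else:
            stat, p, note = float(np.inf), 0.0, "degenerate: zero within-group variance"
    else:
        stat = msb / msw
        p = sps.f.sf(stat, df1, df2)
    return TestResult(
        test_name="one_way_anova",
        statistic=float(stat),
        df=df1,  # numerator df; denominator recoverable from N - k
        p_value=float(p),
        note=note,
    )


def friedman_test(block_matrix) -> TestResult:
    """Friedman rank test for ``blocks x treatments`` data.

    Treatments are ranked within each block with midranks for ties; the
    chi-square statistic carries the standard tie correction and is
    referred to chi-square with (k-1) df.  A matrix constant within every
    block yields statistic 0, p = 1.
    """
    X = np.asarray(block_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidParameterError("need >= 2 blocks and >= 2 treatments")
    b, k = X.shape
    ranks = sps.rankdata(X, axis=1)
    Rj = ranks.sum(axis=0)
    stat = 12.0 / (b * k * (k + 1)) * float((Rj**2).sum()) - 3.0 * b * (k + 1)
    ties = 0.0
    Xs = np.sort(X, axis=1)
    if np.any(Xs[:, 1:] == Xs[:, :-1]):  # tie sizes only matter when ties exist
        for row in X:
            _, counts = np.unique(row, return_counts=True)
            ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (b * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied
        stat, p = 0.0, 1.0
    else:
        stat = max(stat, 0.0) / correction
        p = sps.chi2.sf(stat, k - 1)
    return TestResult(
        test_name="friedman",
        statistic=float(stat),
        df=float(k - 1),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Studentized maximum modulus and Dunnett T3
# ---------------------------------------------------------------------------

def smm_sf(q: float, m: int, df: float) -> float:
    """Survival function of the studentized maximum modulus distribution.

    ``P(max_{i<=m} |Z_i| / S > q)`` with ``Z_i`` iid standard normal and
    ``S = chi_df / sqrt(df)`` shared across the m moduli.  Evaluated by
    quadrature of ``(2 Phi(q s) - 1)^m`` against the density of S; falls
    back to seeded Monte Carlo if the quadrature misbehaves.
    """
    if m < 1 or df <= 0:
        raise InvalidParameterError("need m >= 1 and df > 0")
    if q <= 0:
        return 1.0
    sqdf = np.sqrt(df)

    def integrand(s):
        return (2.0 * sps.norm.cdf(q * s) - 1.0) ** m * sqdf * sps.chi.pdf(s * sqdf, df)

    cdf, err = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-12, limit=300)
    if not np.isfinite(cdf) or err > 1e-6 or not -1e-9 <= cdf <= 1 + 1e-9:
        return smm_sf_mc(q, m, df)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def smm_sf_mc(
    q: float, m: int, df: float, n_draws: int = 10**6, seed: int = SMM_MC_SEED
) -> float:
    """Monte-Carlo estimate of the SMM survival function (fixed seed)."""
    rng = np.random.default_rng(seed)
    # chunked so a 10^6-draw oracle stays within modest memory at m = 15
    exceed = 0
    chunk = max(1, min(n_draws, 200_000))
    done = 0
    while done < n_draws:
        n = min(chunk, n_draws - done)
        z = np.abs(rng.standard_normal((n, m))).max(axis=1)
        s = np.sqrt(rng.chisquare(df, n) / df)
        exceed += int((z / s > q).sum())
        done += n
    return exceed / n_draws


def dunnett_t3(groups: Sequence, labels: Sequence[str] | None = None) -> list[PairwiseResult]:
    """Dunnett's T3 all-pairs comparisons for unequal variances.

    For each pair the statistic is ``|mean_i - mean_j| / sqrt(s_i^2/n_i +
    s_j^2/n_j)`` with Welch–Satterthwaite df; the adjusted p-value refers it
    to the SMM distribution with ``m = k(k-1)/2`` parameters.  Inputs may be
    raw samples or :class:`GroupSummary` objects.
    """
    if len(groups) < 2:
        raise InvalidParameterError("need >= 2 groups")
    if labels is None:
        labels = [getattr(g, "label", str(i)) for i, g in enumerate(groups)]
    summaries = [_as_summary(g, str(lab)) for g, lab in zip(groups, labels)]
    k = len(summaries)
    m = k * (k - 1) // 2
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            A, B = summaries[i], summaries[j]
            se2, df = _welch_terms(A, B)
            diff = A.mean - B.mean
            if se2 == 0:
                stat = 0.0 if diff == 0 else float(np.inf)
                p_adj = 1.0 if diff == 0 else 0.0
                p_un = p_adj
            else:
                stat = abs(diff) / np.sqrt(se2)
                p_adj = smm_sf(stat, m, df)
                p_un = 2.0 * sps.t.sf(stat, df)
            out.append(
                PairwiseResult(
                    group_a=str(labels[i]),
                    group_b=str(labels[j]),
                    mean_difference=float(diff),
                    statistic=float(stat),
                    df=float(df),
                    p_adjusted=float(p_adj),
                    p_unadjusted=float(min(p_un, 1.0)),
                )
            )
    return out


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided t-based p-value.

    ``t = r sqrt((n-2) / (1-r^2))`` referred to t with n-2 df; a perfect
    correlation reports p = 0.  Constant input raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("need equal-length 1-D samples with n >= 3")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = float((dx**2).sum()), float((dy**2).sum())
    if sxx == 0 or syy == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r = float((dx * dy).sum() / np.sqrt(sxx * syy))
    r = min(1.0, max(-1.0, r))
    n = int(x.size)
    if abs(r) == 1.0:
        t_stat = float(np.inf) if r > 0 else float(-np.inf)
        p = 0.0
    else:
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(abs(t_stat), n - 2)
    return CorrelationResult(r=r, n=n, t_statistic=float(t_stat), p_value=float(p))


# ---------------------------------------------------------------------------
# Cohort comparison report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Group summaries, omnibus tests, T3 pairwise table, correlations."""

    control_group: int
    summaries: pd.DataFrame
    omnibus: dict[str, TestResult]
    pairwise: pd.DataFrame
    correlations: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "control_group": self.control_group,
            "summaries": self.summaries.to_dict(orient="records"),
            "omnibus": {
                var: {
                    "test": t.test_name,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                }
                for var, t in self.omnibus.items()
            },
            "pairwise": self.pairwise.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
        }


REPORT_VARIABLES = ("nmve", "cd31_mean", "vegf_mean")


def group_comparison_report(
    cohort: pd.DataFrame, control_group: int = 0
) -> CohortReport:
    """Full statistical report on a cohort table.

    Per variable (normalized MVE and each marker count): per-group n/mean/SD,
    a one-way ANOVA omnibus test across the groups with data, and Dunnett-T3
    all-pairs comparisons with the control contrasts flagged.  Pearson
    correlations relate normalized MVE to each marker count over the animals
    that have an MVE (the occlusive group, lacking one, drops out).
    """
    if control_group not in set(cohort["group_id"]):
        raise ConfigurationError(f"control group {control_group} absent from cohort")
    summaries = []
    pairwise_rows = []
    omnibus: dict[str, TestResult] = {}
    for var in REPORT_VARIABLES:
        sub = cohort[["group_id", var]].dropna()
        by_group = {
            gid: grp[var].to_numpy()
            for gid, grp in sub.groupby("group_id")
            if len(grp) >= 2
        }
        for gid, vals in sorted(by_group.items()):
            s = GroupSummary.from_sample(str(gid), vals)
            summaries.append(
                {"variable": var, "group_id": gid, "n": s.n, "mean": s.mean, "sd": s.sd}
            )
        if len(by_group) >= 2:
            gids = sorted(by_group)
            omnibus[var] = one_way_anova([by_group[g] for g in gids])
            for pr in dunnett_t3(
                [by_group[g] for g in gids], labels=[str(g) for g in gids]
            ):
                pairwise_rows.append(
                    {
                        "variable": var,
                        "group_a": pr.group_a,
                        "group_b": pr.group_b,
                        "mean_difference": pr.mean_difference,
                        "statistic": pr.statistic,
                        "df": pr.df,
                        "p_adjusted": pr.p_adjusted,
                        "p_unadjusted": pr.p_unadjusted,
                        "vs_control": str(control_group) in (pr.group_a, pr.group_b),
                    }
                )
    corr_rows = []
    with_mve = cohort.dropna(subset=["nmve"])
    for marker in ("cd31_mean", "vegf_mean"):
        res = pearson_correlation(
            with_mve["nmve"].to_numpy(), with_mve[marker].to_numpy()
        )
        corr_rows.append(
            {
                "marker": marker,
                "r": res.r,
                "n": res.n,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
            }
        )
    return CohortReport(
        control_group=control_group,
        summaries=pd.DataFrame(summaries),
        omnibus=omnibus,
        pairwise=pd.DataFrame(pairwise_rows),
        correlations=pd.DataFrame(corr_rows),
    )
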