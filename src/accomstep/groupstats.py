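"""Nonparametric group inference across cue conditions.

The analysis path is: label inter-participant outliers per cue with the
1.5 x IQR rule, check the parametric assumptions (Levene homogeneity of
variance, Shapiro-Wilk normality), then test the main effect of cue with
the tie-corrected Kruskal-Wallis H and, when significant, run
Dwass-Steel-Critchlow-Fligner (DSCF) all-pairs comparisons, whose
familywise correction is built in through the studentized-range reference
distribution q_{k, inf}.

Formulas
--------
Kruskal-Wallis (k groups, N pooled observations, mid-ranks R):

    H = [ 12/(N(N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2 ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N)   (t = tie-group sizes),

compared to chi-square with k-1 df.  DSCF for pair (i, j), pooled mid-ranks
r of the n_i + n_j values and rank sum T_j of group j:

    E[T_j] = n_j (n_i + n_j + 1) / 2
    Var    = n_i n_j / ((n_i+n_j)(n_i+n_j-1)) * [ sum r^2 - (n_i+n_j)(n_i+n_j+1)^2 / 4 ]
    W      = sqrt(2) * (T_j - E[T_j]) / sqrt(Var),

with p = P(q_{k, inf} >= |W|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "KWResult",
    "PairwiseResult",
    "AssumptionReport",
    "GroupInference",
    "ranks_with_ties",
    "kruskal_wallis",
    "dscf_pairwise",
    "levene_test",
    "shapiro_wilk",
    "iqr_outliers",
    "main_effect_workflow",
]


@dataclass(frozen=True)
class GroupSample:
    """Participant-level values of one metric for one cue condition."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


def ranks_with_ties(values) -> np.ndarray:
    """Mid-ranks: tied values receive the mean of the ranks they span."""
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    tie_correction: float


def _check_groups(groups: list[GroupSample], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < min_n:
            raise ValueError(f"group {g.label!r} has n={g.n} < {min_n}")


def kruskal_wallis(groups: list[GroupSample]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation.

    All observations identical is a degenerate case (C -> 0) returned as
    H = 0, p = 1.
    """
    _check_groups(groups)
    k = len(groups)
    pooled = np.concatenate([g.values for g in groups])
    N = pooled.size
    ranks = ranks_with_ties(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    C = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (N**3 - N)
    if C == 0.0:  # every pooled value tied
        return KWResult(H=0.0, df=k - 1, p=1.0, tie_correction=0.0)
    start = 0
    ssq = 0.0
    for g in groups:
        r_i = ranks[start:start + g.n]
        start += g.n
        ssq += g.n * (r_i.mean() - (N + 1) / 2.0) ** 2
    H = (12.0 / (N * (N + 1)) * ssq) / C
    p = float(sps.chi2.sf(H, k - 1))
    return KWResult(H=float(H), df=k - 1, p=p, tie_correction=C)


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    W: float
    p: float
    degenerate: bool = False


def _dscf_pair(gi: GroupSample, gj: GroupSample, k: int) -> PairwiseResult:
    ni, nj = gi.n, gj.n
    m = ni + nj
    r = ranks_with_ties(np.concatenate([gi.values, gj.values]))
    Tj = float(r[ni:].sum())
    expect = nj * (m + 1) / 2.0
    var = ni * nj / (m * (m - 1.0)) * (float(np.sum(r**2)) - m * (m + 1.0) ** 2 / 4.0)
    if var <= 0:
        return PairwiseResult(pair=(gi.label, gj.label), W=0.0, p=1.0, degenerate=True)
    W = np.sqrt(2.0) * (Tj - expect) / np.sqrt(var)
    p = float(sps.studentized_range.sf(abs(W), k, np.inf))
    return PairwiseResult(pair=(gi.label, gj.label), W=float(W), p=min(max(p, 0.0), 1.0))


def dscf_pairwise(groups: list[GroupSample]) -> list[PairwiseResult]:
    """DSCF all-pairs comparisons with built-in familywise correction.

    Each pair is ranked in isolation with tie-corrected variance; |W| is
    referred to the studentized-range distribution with k groups and
    infinite df.  p-values are symmetric in pair order and invariant under
    monotone transforms of the pooled data.
    """
    _check_groups(groups)
    k = len(groups)
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            out.append(_dscf_pair(groups[a], groups[b], k))
    return out


def levene_test(groups: list[GroupSample], center: str = "mean") -> tuple[float, float]:
    """Levene's test of homogeneous variance (classical mean-centering).

    ``center="median"`` gives the Brown-Forsythe variant.  A degenerate
    denominator (all absolute deviations equal) returns (0.0, 1.0).
    """
    _check_groups(groups)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    k = len(groups)
    N = sum(g.n for g in groups)
    cfun = np.mean if center == "mean" else np.median
    z = [np.abs(g.values - cfun(g.values)) for g in groups]
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = float(np.concatenate(z).mean())
    num = float(np.sum([g.n for g in groups] * (zbar_i - zbar) ** 2))
    den = float(np.sum([np.sum((zi - zb) ** 2) for zi, zb in zip(z, zbar_i)]))
    if den == 0.0:
        # all within-group deviations identical: no spread information (null)
        # unless the group deviation means still differ (infinite evidence)
        return (0.0, 1.0) if num == 0.0 else (float("inf"), 0.0)
    W = (N - k) / (k - 1.0) * num / den
    p = float(sps.f.sf(W, k - 1, N - k))
    return float(W), p


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston approximation, 3 <= n <= 5000)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if sample.size > 5000:
        raise ValueError("Shapiro-Wilk approximation not valid beyond n=5000")
    res = sps.shapiro(sample)
    return float(res.statistic), float(res.pvalue)


def iqr_outliers(values) -> np.ndarray:
    """1.5 x IQR inter-participant outlier flags.

    Quartiles by linear interpolation of order statistics; x is flagged iff
    x < Q1 - 1.5 IQR or x > Q3 + 1.5 IQR (equality is not outside).  With
    n < 4 no flags are produced (warned).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; IQR outlier rule not applied", stacklevel=2)
        return np.zeros(values.size, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


@dataclass
class AssumptionReport:
    levene_W: float
    levene_p: float
    shapiro: dict[str, tuple[float, float]]  # label -> (W, p)
    alpha: float = 0.05

    @property
    def parametric_ok(self) -> bool:
        if self.levene_p < self.alpha:
            return False
        return all(p >= self.alpha for _, p in self.shapiro.values())


@dataclass
class GroupInference:
    """Full inference for one metric x direction."""

    metric: str
    direction: str
    assumptions: AssumptionReport
    kw: KWResult
    pairwise: list[PairwiseResult] = field(default_factory=list)
    outliers_removed: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def main_effect_significant(self) -> bool:
        return self.kw.p < self.alpha


def main_effect_workflow(groups: list[GroupSample], metric: str = "fa",
                         direction: str = "focus", alpha: float = 0.05,
                         ) -> GroupInference:
    """Outlier labeling -> assumption checks -> KW -> (if significant) DSCF.

    Inter-participant outliers are removed per group by the 1.5 x IQR rule
    before any test.  The DSCF table is produced only when the main effect
    is significant at ``alpha`` (C(k,2) pairs; 21 for the 7-cue design).
    """
    trimmed: list[GroupSample] = []
    removed: dict[str, int] = {}
    for g in groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = iqr_outliers(g.values)
        removed[g.label] = int(flags.sum())
        trimmed.append(GroupSample(g.label, g.values[~flags]))
    _check_groups(trimmed)
    lev_W, lev_p = levene_test(trimmed)
    shapiro = {g.label: shapiro_wilk(g.values) for g in trimmed}
    kw = kruskal_wallis(trimmed)
    pairwise = dscf_pairwise(trimmed) if kw.p < alpha else []
    return GroupInference(
        metric=metric, direction=direction,
        assumptions=AssumptionReport(lev_W, lev_p, shapiro, alpha=alpha),
        kw=kw, pairwise=pairwise, outliers_removed=removed, alpha=alpha,
    )
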