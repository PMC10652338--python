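"""Study statistics as reusable operations.

Implements the statistical recipe used throughout the analyses:
normality-gated two-group testing (Shapiro-Wilk gate, Student's t vs
Mann-Whitney U), a cluster-aware "nested" t-test operating on animal /
patient means, a fixed-lambda Box-Cox transform, one-way ANOVA with Tukey
HSD and a compact letter display, categorical tests (Fisher exact /
chi-square), and four-parameter-logistic (4PL) standard-curve fitting
with inversion for ELISA-style readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ALPHA",
    "BOXCOX_LAMBDA",
    "TestResult",
    "GroupedSample",
    "Logistic4PL",
    "boxcox",
    "boxcox_inverse",
    "choose_two_group_test",
    "nested_t_test",
    "anova_tukey",
    "categorical_test",
    "fit_4pl",
]

ALPHA = 0.05
#: fixed power-transform exponent used for the HA polydispersity comparison
BOXCOX_LAMBDA = -0.4242


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test with its decision trail."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    alpha: float = ALPHA
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


@dataclass(frozen=True)
class GroupedSample:
    """Continuous measurements with the animal/patient each came from.

    ``values[i]`` belongs to cluster ``cluster_id[i]`` within ``group[i]``.
    """

    values: np.ndarray
    cluster_id: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.cluster_id)
        g = np.asarray(self.group)
        if not (len(v) == len(c) == len(g)):
            raise ValueError("values, cluster_id and group must be equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cluster_id", c)
        object.__setattr__(self, "group", g)

    def cluster_means(self) -> pd.DataFrame:
        """One row per cluster: its group and its mean value."""
        df = pd.DataFrame(
            {"value": self.values, "cluster": self.cluster_id, "group": self.group}
        )
        grp = df.groupby("cluster", sort=True)
        out = grp.agg(value=("value", "mean"), group=("group", "first"))
        if (grp["group"].nunique() > 1).any():
            raise ValueError("a cluster spans more than one group")
        return out.reset_index()


# ---------------------------------------------------------------------------
# two-group testing
# ---------------------------------------------------------------------------

def choose_two_group_test(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA
) -> TestResult:
    """Normality-gated two-group comparison.

    Both samples are screened with Shapiro-Wilk at ``alpha``; if both pass,
    a two-sided Student's t-test is used, otherwise Mann-Whitney U.
    Kolmogorov-Smirnov normality p-values are recorded alongside for
    information but do not govern the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")

    sw_x, sw_y = sps.shapiro(x), sps.shapiro(y)
    ks_x = sps.kstest((x - x.mean()) / max(x.std(ddof=1), 1e-300), "norm")
    ks_y = sps.kstest((y - y.mean()) / max(y.std(ddof=1), 1e-300), "norm")
    normal = sw_x.pvalue > alpha and sw_y.pvalue > alpha

    details = {
        "shapiro_p": (float(sw_x.pvalue), float(sw_y.pvalue)),
        "ks_p": (float(ks_x.pvalue), float(ks_y.pvalue)),
        "gate": "both-normal" if normal else "non-normal",
    }
    if normal:
        res = sps.ttest_ind(x, y)
        return TestResult(
            "student-t",
            float(res.statistic),
            float(res.pvalue),
            df=float(x.size + y.size - 2),
            alpha=alpha,
            details=details,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        "mann-whitney-u", float(res.statistic), float(res.pvalue), alpha=alpha,
        details=details,
    )


def nested_t_test(sample: GroupedSample, alpha: float = ALPHA) -> TestResult:
    """Two-sided comparison of two groups on cluster (animal) means.

    Observations within an animal are not independent, so inference runs on
    per-cluster means; degrees of freedom are ``n_clusters - 2``.  For
    balanced designs this is identical to a Student's t-test on cluster
    means (and to nested one-way ANOVA with clusters as subgroups).
    """
    cm = sample.cluster_means()
    groups = cm["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"nested t-test needs exactly 2 groups, got {len(groups)}")
    a = cm.loc[cm["group"] == groups[0], "value"].to_numpy()
    b = cm.loc[cm["group"] == groups[1], "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 clusters per group")
    res = sps.ttest_ind(a, b)
    if np.isnan(res.statistic):  # zero variance on both sides
        stat, p = 0.0, 1.0
    else:
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        "nested-t",
        stat,
        p,
        df=float(len(a) + len(b) - 2),
        alpha=alpha,
        details={"n_clusters": (int(len(a)), int(len(b))),
                 "cluster_means": (a.tolist(), b.tolist())},
    )


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox(y, lmbda: float = BOXCOX_LAMBDA):
    """Power transform ``(y**lmbda - 1) / lmbda`` for positive ``y``.

    Strictly increasing in ``y`` for any non-zero ``lmbda``; ``y = 1``
    maps to 0 exactly.
    """
    if lmbda == 0:
        raise ValueError("lambda must be non-zero")
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    return (np.power(y, lmbda) - 1.0) / lmbda


def boxcox_inverse(z, lmbda: float = BOXCOX_LAMBDA):
    """Inverse of :func:`boxcox`: ``(lmbda*z + 1)**(1/lmbda)``."""
    if lmbda == 0:
        raise ValueError("lambda must be non-zero")
    z = np.asarray(z, dtype=float)
    base = lmbda * z + 1.0
    if np.any(base <= 0):
        raise ValueError("value outside the range of the transform")
    return np.power(base, 1.0 / lmbda)


# ---------------------------------------------------------------------------
# ANOVA + Tukey with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(names: Sequence[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are NOT significantly different; ``different``
    holds unordered pairs that are.
    """
    # start with one letter set containing everyone, split on each difference
    sets: list[set[str]] = [set(names)]
    for a, b in different:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {n: "" for n in names}
    for letter, s in zip(letters, sets):
        for n in names:
            if n in s:
                out[n] += letter
    return out


def anova_tukey(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> tuple[TestResult, pd.DataFrame, dict[str, str]]:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Returns the omnibus F test, a pairwise table (group1, group2, meandiff,
    p_adj, reject) and a compact letter display: groups whose bars carry
    different letters differ significantly.
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey needs >=3 groups; use the two-group path")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    names = [str(n) for n in names]

    f_res = sps.f_oneway(*arrays)
    stat = 0.0 if np.isnan(f_res.statistic) else float(f_res.statistic)
    p = 1.0 if np.isnan(f_res.pvalue) else float(f_res.pvalue)
    k = len(arrays)
    n_tot = sum(len(a) for a in arrays)
    omnibus = TestResult("one-way-anova", stat, p, df=float(k - 1), alpha=alpha,
                         details={"df_within": float(n_tot - k)})

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    if np.all(values == values[0]):
        # degenerate: identical constants, no differences anywhere
        pairs = pd.DataFrame(
            [(a, b, 0.0, 1.0, False) for a, b in combinations(names, 2)],
            columns=["group1", "group2", "meandiff", "p_adj", "reject"],
        )
    else:
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairs = pd.DataFrame(
            tk.summary().data[1:],
            columns=[str(c) for c in tk.summary().data[0]],
        )[["group1", "group2", "meandiff", "p-adj", "reject"]]
        pairs.columns = ["group1", "group2", "meandiff", "p_adj", "reject"]
        pairs["p_adj"] = pairs["p_adj"].astype(float)
        pairs["reject"] = pairs["reject"].astype(bool)

    different = {
        (str(r.group1), str(r.group2)) for r in pairs.itertuples() if r.reject
    }
    letters = _compact_letters(names, different)
    return omnibus, pairs, letters


# ---------------------------------------------------------------------------
# categorical tests
# ---------------------------------------------------------------------------

def categorical_test(table, alpha: float = ALPHA) -> TestResult:
    """Fisher's exact test or chi-square on a 2 x k contingency table.

    For 2 x 2 tables with any expected cell count of five or fewer the
    exact test is used; otherwise Pearson chi-square.  The rule taken is
    recorded in ``details``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")

    expected = sps.contingency.expected_freq(table)
    if table.shape == (2, 2) and expected.min() <= 5:
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult(
            "fisher-exact", float(odds), float(p), alpha=alpha,
            details={"rule": "2x2 with expected count <= 5",
                     "min_expected": float(expected.min())},
        )
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        "chi-square", float(chi2), float(p), df=float(dof), alpha=alpha,
        details={"rule": "expected counts > 5 or table wider than 2x2",
                 "min_expected": float(expected.min())},
    )


# ---------------------------------------------------------------------------
# 4PL calibration
# ---------------------------------------------------------------------------

def _four_pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + np.power(x / c, b))


@dataclass(frozen=True)
class Logistic4PL:
    """Four-parameter logistic curve ``y = d + (a-d)/(1+(x/c)**b)``.

    ``a`` is the response at zero concentration, ``d`` the response at
    infinite concentration, ``c`` the inflection concentration and ``b``
    the slope factor.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection concentration c must be positive")

    def predict(self, conc):
        return _four_pl(np.asarray(conc, dtype=float), self.a, self.b, self.c, self.d)

    def invert(self, resp):
        """Map readings back to concentrations.

        Readings at or beyond the asymptotes are flagged out-of-range and
        reported as NaN.
        """
        resp = np.atleast_1d(np.asarray(resp, dtype=float))
        lo, hi = min(self.a, self.d), max(self.a, self.d)
        in_range = (resp > lo) & (resp < hi)
        conc = np.full(resp.shape, np.nan)
        r = resp[in_range]
        with np.errstate(all="ignore"):
            conc[in_range] = self.c * np.power(
                (self.a - self.d) / (r - self.d) - 1.0, 1.0 / self.b
            )
        return conc, ~in_range


def fit_4pl(conc, resp) -> Logistic4PL:
    """Least-squares 4PL fit of a standard curve.

    ``conc`` must be strictly positive standard concentrations and ``resp``
    the corresponding readings.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.size != resp.size or conc.size < 4:
        raise ValueError("need >= 4 matched (concentration, response) standards")
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")

    order = np.argsort(conc)
    a0 = float(resp[order[0]])
    d0 = float(resp[order[-1]])
    c0 = float(np.exp(np.mean(np.log(conc))))
    b0 = 1.0 if d0 > a0 else -1.0
    popt, _ = optimize.curve_fit(
        _four_pl, conc, resp, p0=[a0, b0, c0, d0], maxfev=20000
    )
    a, b, c, d = (float(v) for v in popt)
    if b < 0:  # mirrored parameterisation: same curve with a/d swapped
        a, b, d = d, -b, a
    return Logistic4PL(a=a, b=b, c=c, d=d)
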