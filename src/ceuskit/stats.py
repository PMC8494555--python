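"""Cohort statistics: diagnostic metrics, group tests, power simulation.

Group comparisons of perfusion indicators use Welch's unequal-variance
t-test (no homogeneity assumption); proportions use Pearson's chi-square
without continuity correction.  Each comparison is judged at the
per-comparison P < 0.05 rule; an optional Holm correction is available but
off by default.  Diagnostic metrics are exact rational arithmetic on a 2x2
confusion matrix (positive = malignant), rendered to two decimals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .errors import InvalidInputError, UndefinedMetricError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diagnostic metrics


@dataclass(frozen=True)
class DiagnosticCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise InvalidInputError("confusion matrix is empty")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages; exact fractions retained for invariant checks."""

    sensitivity: float
    specificity: float
    accuracy: float
    PPV: float
    NPV: float
    exact: dict = None  # metric name -> Fraction

    def rounded(self) -> dict:
        return {
            k: round(getattr(self, k), 2)
            for k in ("sensitivity", "specificity", "accuracy", "PPV", "NPV")
        }


def diagnostic_metrics(counts: DiagnosticCounts) -> DiagnosticMetrics:
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denoms = {
        "sensitivity": tp + fn,
        "specificity": tn + fp,
        "PPV": tp + fp,
        "NPV": tn + fn,
    }
    for name, d in denoms.items():
        if d == 0:
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
    exact = {
        "sensitivity": Fraction(100 * tp, tp + fn),
        "specificity": Fraction(100 * tn, tn + fp),
        "accuracy": Fraction(100 * (tp + tn), tp + fp + tn + fn),
        "PPV": Fraction(100 * tp, tp + fp),
        "NPV": Fraction(100 * tn, tn + fn),
    }
    return DiagnosticMetrics(
        sensitivity=float(exact["sensitivity"]),
        specificity=float(exact["specificity"]),
        accuracy=float(exact["accuracy"]),
        PPV=float(exact["PPV"]),
        NPV=float(exact["NPV"]),
        exact=exact,
    )


# ---------------------------------------------------------------------------
# hypothesis tests


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    test: str
    group1: str
    group2: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    statistic: float
    df: float
    p_value: float
    direction: int          # sign of (mean1 - mean2)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def welch_t_test(
    a, b, parameter: str = "", labels: tuple[str, str] = ("group1", "group2")
) -> GroupComparison:
    """Welch's two-sample t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("samples must be finite")
    m1, m2 = float(np.mean(a)), float(np.mean(b))
    v1, v2 = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    n1, n2 = len(a), len(b)
    se2 = v1 / n1 + v2 / n2
    degenerate = False
    if se2 == 0.0:
        stat, df, p = 0.0, float(n1 + n2 - 2), 1.0
        degenerate = True
    else:
        stat = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * float(sps.t.sf(abs(stat), df))
    return GroupComparison(
        parameter=parameter, test="welch-t",
        group1=labels[0], group2=labels[1],
        mean1=m1, sd1=math.sqrt(v1), n1=n1,
        mean2=m2, sd2=math.sqrt(v2), n2=n2,
        statistic=stat, df=df, p_value=min(p, 1.0),
        direction=int(np.sign(m1 - m2)), degenerate=degenerate,
    )


def paired_t_test(
    x, y, parameter: str = "", labels: tuple[str, str] = ("x", "y")
) -> GroupComparison:
    """One-sample t-test on paired differences, two-sided.

    Zero-variance differences are degenerate: all-zero differences report
    statistic 0 with p = 1; constant nonzero differences report an infinite
    statistic with p -> 0, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("paired samples must have equal length")
    if len(x) < 2:
        raise InvalidInputError("need at least 2 pairs")
    d = x - y
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    n = len(d)
    df = float(n - 1)
    if sd == 0.0:
        if md == 0.0:
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, md), 0.0
        degenerate = True
    else:
        stat = md / (sd / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(stat), df))
        degenerate = False
    return GroupComparison(
        parameter=parameter, test="paired-t",
        group1=labels[0], group2=labels[1],
        mean1=float(np.mean(x)), sd1=float(np.std(x, ddof=1)), n1=n,
        mean2=float(np.mean(y)), sd2=float(np.std(y, ddof=1)), n2=n,
        statistic=stat, df=df, p_value=min(p, 1.0),
        direction=int(np.sign(md)), degenerate=degenerate,
    )


def chi_square_test(table, correction: bool = False) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidInputError("chi-square test expects a 2x2 table")
    if np.any(t < 0):
        raise InvalidInputError("cell counts must be non-negative")
    n = t.sum()
    if n <= 0:
        raise InvalidInputError("table total must be positive")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise InvalidInputError("zero marginal total")
    a, b = t[0]
    c, d = t[1]
    delta = abs(a * d - b * c)
    if correction:
        delta = max(delta - n / 2.0, 0.0)
    stat = n * delta**2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(sps.chi2.sf(stat, 1))
    p1 = a / rows[0]
    p2 = c / rows[1]
    return GroupComparison(
        parameter="proportion", test="chi-square",
        group1="row1", group2="row2",
        mean1=p1, sd1=float(np.sqrt(p1 * (1 - p1))), n1=int(rows[0]),
        mean2=p2, sd2=float(np.sqrt(p2 * (1 - p2))), n2=int(rows[1]),
        statistic=float(stat), df=1.0, p_value=p,
        direction=int(np.sign(p1 - p2)),
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default elsewhere)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


# ---------------------------------------------------------------------------
# cohort-level comparisons


def compare_groups(table, parameter: str, group_col: str = "group"):
    """Pairwise Welch tests of one indicator across all groups in a table.

    ``table`` is a DataFrame with a group-label column and one column per
    indicator (as produced by the curve quantifier); rows with a missing
    value for ``parameter`` (e.g. missing-washout K_DOWN) are dropped with a
    logged count.  Returns a list of :class:`GroupComparison`, one per
    unordered group pair.
    """
    import pandas as pd

    if parameter not in table.columns:
        raise InvalidInputError(f"parameter {parameter!r} not in table")
    sub = table[[group_col, parameter]]
    n_missing = int(sub[parameter].isna().sum())
    if n_missing:
        logger.info(
            "dropping %d subjects with missing %s", n_missing, parameter
        )
        sub = sub.dropna(subset=[parameter])
    groups = sorted(sub[group_col].unique())
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups with data")
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            a = sub.loc[sub[group_col] == g1, parameter].to_numpy()
            b = sub.loc[sub[group_col] == g2, parameter].to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise InvalidInputError(
                    f"group {g1 if len(a) < 2 else g2!r} has < 2 usable subjects"
                )
            out.append(welch_t_test(a, b, parameter=parameter, labels=(g1, g2)))
    return out


def comparisons_table(comparisons):
    """Render a list of GroupComparison as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": c.parameter, "test": c.test,
                "group1": c.group1, "group2": c.group2,
                "mean1": c.mean1, "sd1": c.sd1, "n1": c.n1,
                "mean2": c.mean2, "sd2": c.sd2, "n2": c.n2,
                "statistic": c.statistic, "df": c.df, "p_value": c.p_value,
                "direction": c.direction, "significant": c.significant,
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class NormalEffectSpec:
    """Two-group normal effect for power simulation: mean shift in SD units."""

    delta: float            # mean difference, same units as sd
    sd: float = 1.0
    n_per_group: int = 30


def closed_form_power(delta: float, sd: float, n: int, alpha: float = 0.05) -> float:
    """Exact two-sample t power via the noncentral t distribution."""
    ncp = delta / (sd * math.sqrt(2.0 / n))
    df = 2 * n - 2
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def power_simulation(spec, n_reps: int = 400, alpha: float = 0.05, seed: int = 0):
    """Monte-Carlo power of the Welch test per indicator.

    With a :class:`NormalEffectSpec`, each replicate draws two normal
    samples and tests them.  With a two-group cohort spec, each replicate
    draws per-subject bolus parameters and tests the closed-form indicator
    values (TTP, I_max, AUC); this measures whether the configured group
    sizes can detect the configured effects before curve noise enters.
    Returns ``{parameter: {"power": p, "mc_se": se}}``.
    """
    if n_reps < 100:
        raise InvalidInputError("n_reps must be at least 100")
    rng = np.random.default_rng(seed)
    hits: dict[str, int] = {}

    if isinstance(spec, NormalEffectSpec):
        n = spec.n_per_group
        for _ in range(n_reps):
            a = rng.normal(0.0, spec.sd, size=n)
            b = rng.normal(spec.delta, spec.sd, size=n)
            res = welch_t_test(a, b)
            hits["delta"] = hits.get("delta", 0) + (res.p_value < alpha)
    else:
        from .synthetic import CohortSpec, _lognormal_multipliers  # local import

        if not isinstance(spec, CohortSpec):
            raise InvalidInputError(
                "spec must be a CohortSpec or NormalEffectSpec"
            )
        spec.validate()
        labels = sorted(spec.group_param_means)
        if len(labels) != 2:
            raise InvalidInputError("cohort power needs exactly two groups")
        indicators = ("TTP", "I_max", "AUC")
        for _ in range(n_reps):
            values = {lab: {k: [] for k in indicators} for lab in labels}
            for lab in labels:
                mean = spec.group_param_means[lab]
                n = spec.size_of(lab)
                mult = {
                    name: _lognormal_multipliers(rng, spec.between_subject_cv, n)
                    for name in ("t0", "beta", "A")
                }
                t0 = mean.t0 * mult["t0"]
                al = mean.alpha * np.ones(n)
                be = mean.beta * mult["beta"]
                amp = mean.A * mult["A"]
                ttp = t0 + al * be
                peak = amp * (al * be) ** al * np.exp(-al)
                auc = amp * be ** (al + 1) * np.exp(gammaln(al + 1))
                values[lab]["TTP"] = ttp
                values[lab]["I_max"] = mean.baseline + peak
                values[lab]["AUC"] = auc
            for k in indicators:
                res = welch_t_test(values[labels[0]][k], values[labels[1]][k])
                hits[k] = hits.get(k, 0) + (res.p_value < alpha)

    out = {}
    for k, h in hits.items():
        p = h / n_reps
        out[k] = {"power": p, "mc_se": math.sqrt(max(p * (1 - p), 1e-12) / n_reps)}
    return out
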