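"""Diagnostic-accuracy engine: ROC/AUC, DeLong comparison, Youden cut-offs,
exact-CI contingency summaries, combined / sequential two-modality
classification, concordance stratification and patient-wise aggregation.

Conventions: a lesion is called positive when its parameter value is
*strictly greater* than the cut-off; Youden ties are broken toward the lower
cut-off (favouring sensitivity).  Proportion confidence intervals are exact
Clopper–Pearson; the odds-ratio interval is the exact conditional (Fisher)
interval with unbounded limits rendered "n.a.".  A normal-approximation
alternative is available for both.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .outcomes import NON_EVALUABLE, PROGRESSIVE, patient_outcome

__all__ = [
    "ROCCurve",
    "roc_auc",
    "logistic_combine",
    "delong_test",
    "youden_cutoff",
    "ClassificationRule",
    "classify_lesions",
    "ContingencyTable",
    "DiagnosticSummary",
    "summarize_contingency",
    "concordance_matrix",
    "patientwise_analysis",
    "evaluate_parameter",
    "diagnostic_report",
]


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ROCCurve:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        return ax


def _check_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """Rank-based (Mann–Whitney) AUC with tie correction, plus curve points.

    For multi-covariate scores fit :func:`logistic_combine` first and pass
    the linear predictor here.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    _check_classes(y)
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(s[y] > t).mean() for t in thresholds])
    fpr = np.array([(s[~y] > t).mean() for t in thresholds])
    return ROCCurve(float(auc), fpr, tpr, thresholds)


def logistic_combine(
    covariates: pd.DataFrame, labels: Sequence[bool]
) -> np.ndarray:
    """Maximum-likelihood logistic linear predictor for ROC construction.

    On perfect separation (the MLE diverges) falls back to the single
    covariate with the highest rank AUC, with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = pd.DataFrame(covariates).astype(float)
    if x.isna().any().any():
        raise ValueError("missing covariate values")
    y = np.asarray(labels, dtype=bool)
    _check_classes(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
        lp = np.asarray(fit.fittedvalues)
        if not np.isfinite(fit.params).all() or not fit.mle_retvals.get("converged", True):
            raise PerfectSeparationError("diverging coefficients")
        prob = np.asarray(fit.predict())
        if prob[y].min() > 1 - 1e-6 and prob[~y].max() < 1e-6:
            raise PerfectSeparationError("perfect in-sample separation")
        return lp
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning, Exception):
        aucs = {c: roc_auc(x[c].to_numpy(), y).auc for c in x.columns}
        best = max(aucs, key=lambda c: aucs[c])
        warnings.warn(
            f"logistic fit did not converge (separation?); using rank AUC of '{best}'"
        )
        return x[best].to_numpy()


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """DeLong test of equality of two correlated (paired) ROC AUCs.

    Returns (AUC_a - AUC_b, two-sided p-value from the normal reference).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (sa.shape == sb.shape == y.shape):
        raise ValueError("paired scores must cover identical lesions")
    _check_classes(y)

    def placements(s):
        pos, neg = s[y], s[~y]
        # V10[i] = P(pos_i > neg) with ties 1/2; V01[j] analogous
        v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / neg.size for p in pos])
        v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / pos.size for q in neg])
        return v10, v01

    v10a, v01a = placements(sa)
    v10b, v01b = placements(sb)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = float(auc_a - auc_b)
    if var <= 0 or not np.isfinite(var):
        if delta == 0.0:
            return 0.0, 1.0
        warnings.warn("degenerate DeLong variance; p-value set to 1")
        return delta, 1.0
    z = delta / np.sqrt(var)
    return delta, float(2.0 * stats.norm.sf(abs(z)))


def delong_variance(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> float:
    """Variance of AUC_a - AUC_b from the DeLong placement covariances."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos_a, neg_a = sa[y], sa[~y]
    pos_b, neg_b = sb[y], sb[~y]
    v10 = lambda pos, neg: np.array(
        [((p > neg).sum() + 0.5 * (p == neg).sum()) / neg.size for p in pos]
    )
    v01 = lambda pos, neg: np.array(
        [((pos > q).sum() + 0.5 * (pos == q).sum()) / pos.size for q in neg]
    )
    s10 = np.cov(np.stack([v10(pos_a, neg_a), v10(pos_b, neg_b)]))
    s01 = np.cov(np.stack([v01(pos_a, neg_a), v01(pos_b, neg_b)]))
    m, n = pos_a.size, neg_a.size
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, float]:
    """Cut-off maximising Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values under the strict 'value >
    cut-off is positive' convention; ties are broken toward the lower
    cut-off (higher sensitivity).  Returns (cut-off, J).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_classes(y)
    cands = np.unique(s)
    n1, n0 = y.sum(), (~y).sum()
    best_c, best_j = None, -np.inf
    for c in cands:  # ascending => the first maximiser is the lowest cut-off
        sens = (s[y] > c).sum() / n1
        spec = (s[~y] <= c).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = float(c), float(j)
    return best_c, best_j


# --------------------------------------------------------------------------
# Classification rules
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ClassificationRule:
    """Threshold rule for one parameter, with separate cut-offs for
    contrast-enhancing and non-enhancing lesions (value > cut-off is
    positive).  ``mode`` documents how the rule is meant to be combined."""

    parameter: str
    cutoff_ce: float
    cutoff_non_ce: float | None = None
    mode: Literal["single", "concordant-AND", "sequential-BV-first"] = "single"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff_ce):
            raise ValueError("cut-off must be finite")
        if self.cutoff_non_ce is not None and not np.isfinite(self.cutoff_non_ce):
            raise ValueError("cut-off must be finite")

    def cutoff_for(self, enhancing: bool) -> float:
        if not enhancing and self.cutoff_non_ce is not None:
            return self.cutoff_non_ce
        return self.cutoff_ce


@dataclasses.dataclass
class ClassificationResult:
    calls: pd.Series  # boolean per lesion (index matches the table)
    mode: str
    second_test_avoided: float | None = None  # sequential mode only


def _single_calls(table: pd.DataFrame, rule: ClassificationRule) -> pd.Series:
    if rule.parameter not in table.columns:
        raise ValueError(f"parameter '{rule.parameter}' not in table")
    vals = table[rule.parameter].astype(float)
    missing = vals.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} lesion(s) missing '{rule.parameter}' excluded"
        )
    if rule.cutoff_non_ce is not None and "enhancing" not in table.columns:
        raise ValueError("enhancing flag required when CE/non-CE cut-offs differ")
    if "enhancing" in table.columns and rule.cutoff_non_ce is not None:
        cut = table["enhancing"].astype(bool).map(
            {True: rule.cutoff_ce, False: rule.cutoff_non_ce}
        )
    else:
        cut = pd.Series(rule.cutoff_ce, index=table.index)
    calls = vals > cut
    return calls.where(~missing, other=pd.NA)


def classify_lesions(
    table: pd.DataFrame,
    rule: ClassificationRule,
    secondary: ClassificationRule | None = None,
) -> ClassificationResult:
    """Apply a classification rule to a lesion table.

    mode 'single': threshold by CE status.  'concordant-AND': positive only
    if positive on both ``rule`` and ``secondary``.  'sequential-BV-first':
    ``rule`` is the BV rule applied to every lesion; the ``secondary``
    (PET) rule decides only lesions negative on BV, and the fraction of
    lesions whose second test was not needed (BV-positive) is reported.
    """
    calls = _single_calls(table, rule)
    if rule.mode == "single":
        return ClassificationResult(calls, "single")
    if secondary is None:
        raise ValueError(f"mode '{rule.mode}' needs a secondary rule")
    other = _single_calls(table, secondary)
    if rule.mode == "concordant-AND":
        return ClassificationResult(
            (calls.astype("boolean") & other.astype("boolean")), "concordant-AND"
        )
    if rule.mode == "sequential-BV-first":
        bv, fet = calls.astype("boolean"), other.astype("boolean")
        final = bv | (~bv & fet)
        avoided = float(bv.fillna(False).mean())
        return ClassificationResult(final, "sequential-BV-first", avoided)
    raise ValueError(f"unknown mode '{rule.mode}'")


# --------------------------------------------------------------------------
# Contingency summaries with exact confidence intervals
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_calls(cls, calls: Sequence[bool], truth: Sequence[bool]) -> "ContingencyTable":
        c = np.asarray(pd.array(calls, dtype="boolean"))
        t = np.asarray(truth, dtype=bool)
        keep = ~pd.isna(c)
        c = c[keep].astype(bool)
        t = t[keep]
        return cls(
            tp=int((c & t).sum()),
            fp=int((c & ~t).sum()),
            fn=int((~c & t).sum()),
            tn=int((~c & ~t).sum()),
        )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n == 0:
        return (np.nan, np.nan)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _wald_proportion(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(p * (1 - p) / n)
    return max(p - z * se, 0.0), min(p + z * se, 1.0)


def exact_odds_ratio_ci(
    tp: int, fp: int, fn: int, tn: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact conditional (Fisher) confidence interval for the odds ratio.

    Inverts the tails of Fisher's noncentral hypergeometric distribution of
    the TP count given the table margins; limits at the support boundary are
    infinite (rendered "n.a." downstream) or zero.
    """
    total = tp + fp + fn + tn
    row1 = tp + fp          # predicted positive
    col1 = tp + fn          # truly positive
    x = tp
    lo_support = max(0, col1 - (total - row1))
    hi_support = min(row1, col1)
    if total == 0 or row1 in (0, total) or col1 in (0, total):
        return (np.nan, np.nan)

    def sf(psi):  # P(X >= x | psi)
        return stats.nchypergeom_fisher.sf(x - 1, total, row1, col1, psi)

    def cdf(psi):  # P(X <= x | psi)
        return stats.nchypergeom_fisher.cdf(x, total, row1, col1, psi)

    if x == lo_support:
        lower = 0.0
    else:
        lower = float(
            np.exp(brentq(lambda t: sf(np.exp(t)) - alpha / 2, -50.0, 50.0, xtol=1e-10))
        )
    if x == hi_support:
        upper = np.inf
    else:
        upper = float(
            np.exp(brentq(lambda t: cdf(np.exp(t)) - alpha / 2, -50.0, 50.0, xtol=1e-10))
        )
    return lower, upper


@dataclasses.dataclass
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV (%) and odds ratio, with 95% CIs.

    Undefined quantities (division by zero, unbounded exact limits) are NaN /
    inf internally and rendered "n.a." by :meth:`format_value` — never an
    exception.  Optionally carries AUC, cut-off and Youden J when produced by
    :func:`evaluate_parameter`.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    odds_ratio: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple
    npv_ci: tuple
    odds_ratio_ci: tuple
    accuracy: float
    table: ContingencyTable
    auc: float | None = None
    auc_se: float | None = None
    cutoff: float | None = None
    youden_j: float | None = None

    @staticmethod
    def format_value(v: float, digits: int = 1) -> str:
        if v is None or not np.isfinite(v):
            return "n.a."
        return f"{v:.{digits}f}"

    def format_cell(self, name: str) -> str:
        v = getattr(self, name)
        lo, hi = getattr(self, name + "_ci")
        f = self.format_value
        return f"{f(v)} ({f(lo)}–{f(hi)})"

    def summary(self) -> str:
        rows = [
            ("Sensitivity (%)", self.format_cell("sensitivity")),
            ("Specificity (%)", self.format_cell("specificity")),
            ("PPV (%)", self.format_cell("ppv")),
            ("NPV (%)", self.format_cell("npv")),
            ("Odds ratio", self.format_cell("odds_ratio")),
            ("Correctly classified (%)", self.format_value(self.accuracy)),
        ]
        if self.auc is not None:
            rows.insert(0, ("ROC AUC", self.format_value(self.auc, 2)))
        if self.cutoff is not None:
            rows.insert(1, ("Cut-off", self.format_value(self.cutoff, 2)))
        w = max(len(r[0]) for r in rows)
        return "\n".join(f"{k:<{w}}  {v}" for k, v in rows)


def summarize_contingency(
    table: ContingencyTable,
    alpha: float = 0.05,
    ci_method: Literal["exact", "normal"] = "exact",
) -> DiagnosticSummary:
    """Sens/spec/PPV/NPV (%), odds ratio and exact 95% CIs from a 2x2 table."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    prop_ci = clopper_pearson if ci_method == "exact" else _wald_proportion

    def pct(k, n):
        return 100.0 * k / n if n > 0 else np.nan

    def pct_ci(k, n):
        lo, hi = prop_ci(k, n, alpha)
        return (100.0 * lo, 100.0 * hi)

    if fp * fn > 0:
        odds = tp * tn / (fp * fn)
    elif tp * tn > 0:
        odds = np.inf
    else:
        odds = np.nan
    if ci_method == "exact":
        or_ci = exact_odds_ratio_ci(tp, fp, fn, tn, alpha)
    else:
        if min(tp, fp, fn, tn) > 0:
            se = np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
            z = stats.norm.ppf(1 - alpha / 2)
            or_ci = (odds * np.exp(-z * se), odds * np.exp(z * se))
        else:
            or_ci = (np.nan, np.nan)
    return DiagnosticSummary(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        odds_ratio=odds,
        sensitivity_ci=pct_ci(tp, tp + fn),
        specificity_ci=pct_ci(tn, tn + fp),
        ppv_ci=pct_ci(tp, tp + fp),
        npv_ci=pct_ci(tn, tn + fn),
        odds_ratio_ci=or_ci,
        accuracy=pct(tp + tn, table.n),
        table=table,
    )


# --------------------------------------------------------------------------
# Concordance and patient-wise aggregation
# --------------------------------------------------------------------------

def concordance_matrix(
    table: pd.DataFrame,
    rule_fet: ClassificationRule,
    rule_bv: ClassificationRule,
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """2x2 stratification by PET/BV positivity with progression fractions.

    Rows FET-/FET+, columns BV-/BV+; each cell holds the number progressive,
    the cell total and the percentage.  Cell totals partition the cohort.
    """
    fet = _single_calls(table, rule_fet).astype("boolean")
    bv = _single_calls(table, rule_bv).astype("boolean")
    prog = table[outcome_col].eq(PROGRESSIVE)
    rows = []
    for f_pos in (False, True):
        for b_pos in (False, True):
            in_cell = (fet == f_pos) & (bv == b_pos)
            n = int(in_cell.sum())
            k = int((in_cell & prog).sum())
            rows.append(
                {
                    "fet": "FET+" if f_pos else "FET-",
                    "bv": "BV+" if b_pos else "BV-",
                    "n_progressive": k,
                    "n_total": n,
                    "pct_progressive": 100.0 * k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def patientwise_analysis(
    table: pd.DataFrame,
    parameter: str,
    outcome_col: str = "outcome",
    patient_outcome_col: str = "patient_outcome",
) -> pd.DataFrame:
    """Per-patient maximal parameter value and patient-level outcome.

    The score is the maximum across *all* the patient's lesions (lesions
    without a lesion-wise outcome still contribute their value); the outcome
    is progressive if any lesion is progressive, non-progressive if all
    evaluable lesions are non-progressive.  An explicit per-patient override
    column, when present, wins (it models chart-level non-evaluability).
    Non-evaluable patients are excluded.
    """
    rows = []
    for pid, grp in table.groupby("patient_id", sort=True):
        if patient_outcome_col in grp.columns and grp[patient_outcome_col].notna().any():
            label = str(grp[patient_outcome_col].dropna().iloc[0])
        else:
            label = patient_outcome(list(grp[outcome_col]))
        if label == NON_EVALUABLE:
            continue
        rows.append(
            {
                "patient_id": pid,
                parameter: float(grp[parameter].max()),
                "outcome": label,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Per-parameter evaluation rows (accuracy-table style)
# --------------------------------------------------------------------------

def evaluate_parameter(
    table: pd.DataFrame,
    parameter: str,
    outcome_col: str = "outcome",
    cutoffs: tuple[float, float | None] | None = None,
) -> DiagnosticSummary:
    """ROC AUC, Youden-optimal cut-off and cut-off diagnostics for one
    parameter over a lesion table (rows with non-evaluable outcome are
    dropped).  Pre-specified (CE, non-CE) cut-offs may be supplied to mirror
    the combined-criteria analysis."""
    df = table[table[outcome_col] != NON_EVALUABLE].dropna(subset=[parameter])
    y = df[outcome_col].eq(PROGRESSIVE).to_numpy()
    s = df[parameter].to_numpy(dtype=float)
    roc = roc_auc(s, y)
    if cutoffs is None:
        cut, j = youden_cutoff(s, y)
        rule = ClassificationRule(parameter, cut)
    else:
        rule = ClassificationRule(parameter, cutoffs[0], cutoffs[1])
        cut = cutoffs[0]
        j = None
    calls = classify_lesions(df, rule).calls
    summ = summarize_contingency(ContingencyTable.from_calls(calls, y))
    summ.auc = roc.auc
    summ.cutoff = cut
    if j is None:
        j = summ.sensitivity / 100.0 + summ.specificity / 100.0 - 1.0
    summ.youden_j = j
    return summ


def diagnostic_report(
    table: pd.DataFrame,
    parameters: Sequence[str],
    outcome_col: str = "outcome",
) -> pd.DataFrame:
    """One accuracy-table row per parameter: AUC, optimal cut-off, sens/spec/
    OR/PPV/NPV with exact CIs."""
    rows = []
    for p in parameters:
        s = evaluate_parameter(table, p, outcome_col)
        rows.append(
            {
                "parameter": p,
                "auc": s.auc,
                "cutoff": s.cutoff,
                "youden_j": s.youden_j,
                "sensitivity": s.format_cell("sensitivity"),
                "specificity": s.format_cell("specificity"),
                "odds_ratio": s.format_cell("odds_ratio"),
                "ppv": s.format_cell("ppv"),
                "npv": s.format_cell("npv"),
            }
        )
    return pd.DataFrame(rows)
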