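"""Subject-level diagnostic evaluation of single and combined criteria.

Given per-subject boolean decisions (one column per named criterion) and a
patient/control truth label, this module computes 2x2 counts with
sensitivity, specificity, accuracy, PPV and NPV; combines criteria under
any-k-of-n rules; and compares continuous per-subject scores by ROC AUC
(rank/concordance formulation with half-credit for ties), including the
DeLong test for paired AUCs, the McNemar test on discordant pairs, and
Cochran's Q across three or more criteria.

Criteria can be evaluable on different subject subsets (e.g. LGE evaluable in
only 35 of 50 controls); a missing decision is encoded as NaN and the
affected subject is dropped from that criterion's 2x2 table and from any
combination that needs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticSummary:
    """2x2 counts and the five standard metrics (percent, unrounded)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_patients(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return _pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def ppv(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _pct(self.tn, self.tn + self.fn)

    def rounded(self) -> Dict[str, float]:
        """Display metrics rounded half-up to integers, as printed in tables."""
        return {
            k: float(np.floor(v + 0.5)) if np.isfinite(v) else np.nan
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "ppv": self.ppv,
                "npv": self.npv,
            }.items()
        }


def _pct(num: int, den: int) -> float:
    if den == 0:
        logger.warning("zero evaluable subjects in an arm; metric missing")
        return float("nan")
    return 100.0 * num / den


def summarize_criterion(decisions: pd.Series, truth: pd.Series) -> DiagnosticSummary:
    """2x2 summary of a boolean decision vector against patient/control truth.

    ``decisions`` may hold NaN for non-evaluable subjects; those subjects are
    dropped. ``truth`` is boolean (True = patient) and must cover every
    decision index.
    """
    if truth.isna().any():
        raise ValueError("missing truth labels")
    d = decisions.dropna().astype(bool)
    t = truth.loc[d.index].astype(bool)
    return DiagnosticSummary(
        tp=int((d & t).sum()),
        fp=int((d & ~t).sum()),
        tn=int((~d & ~t).sum()),
        fn=int((~d & t).sum()),
    )


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      n_patients: int, n_controls: int) -> DiagnosticSummary:
    """Reconstruct 2x2 counts from printed sensitivity/specificity and arm sizes."""
    tp = int(round(sensitivity_pct / 100.0 * n_patients))
    tn = int(round(specificity_pct / 100.0 * n_controls))
    return DiagnosticSummary(tp=tp, fp=n_controls - tn, tn=tn, fn=n_patients - tp)


def combine_criteria(decisions: pd.DataFrame, k: int) -> pd.Series:
    """Any-k-of-n combination of boolean criterion columns.

    True iff at least ``k`` of the n constituent decisions are true; ``k = n``
    is the all-n (AND) rule, ``k = 1`` the OR rule. Subjects with any missing
    constituent are dropped (logged).
    """
    n = decisions.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    complete = decisions.dropna()
    dropped = len(decisions) - len(complete)
    if dropped:
        logger.info("combination %d-of-%d: %d subjects dropped (incomplete criteria)",
                    k, n, dropped)
    return (complete.astype(bool).sum(axis=1) >= k)


def roc_auc(scores: pd.Series | np.ndarray, truth: pd.Series | np.ndarray) -> float:
    """AUC by the rank (concordance / Mann-Whitney) formulation, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one subject per class")
    if np.ptp(scores) == 0:
        logger.warning("constant scores: AUC degenerates to 0.5")
        return 0.5
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def _placements(pos: np.ndarray, neg: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one score vector."""
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per-patient placements
    v01 = cmp.mean(axis=0)  # per-control placements
    return v10, v01, float(cmp.mean())


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    truth: Sequence[bool],
) -> Tuple[float, float, float, float]:
    """DeLong comparison of two paired AUCs: returns (auc_a, auc_b, z, p).

    The variance-covariance of the paired AUCs is estimated from placement
    values; the two-sided p comes from the normal approximation. A degenerate
    variance yields NaN z/p with a diagnostic, except in the exact-equality
    case where z = 0, p = 1.
    """
    truth = np.asarray(truth, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != truth.shape:
        raise ValueError("scores and truth must be paired on identical subjects")
    v10a, v01a, auc_a = _placements(a[truth], a[~truth])
    v10b, v01b, auc_b = _placements(b[truth], b[~truth])
    m, n = truth.sum(), (~truth).sum()
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, 0.0, 1.0
        logger.warning("degenerate DeLong variance; p missing")
        return auc_a, auc_b, float("nan"), float("nan")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(min(p, 1.0))


def mcnemar_test(
    decisions_a: Sequence[bool],
    decisions_b: Sequence[bool],
    exact_max_discordant: int = 25,
) -> float:
    """McNemar test on paired binary decisions; returns the two-sided p.

    Uses the exact binomial test on the discordant pairs when their number is
    below ``exact_max_discordant``, otherwise the chi-square approximation
    with continuity correction. Zero discordant pairs give p = 1.
    """
    a = np.asarray(decisions_a, dtype=bool)
    b = np.asarray(decisions_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired decision vectors must align")
    n01 = int((a & ~b).sum())
    n10 = int((~a & b).sum())
    n_disc = n01 + n10
    if n_disc == 0:
        return 1.0
    if n_disc < exact_max_discordant:
        # two-sided by doubling the smaller tail, capped at 1
        p = 2.0 * stats.binom.cdf(min(n01, n10), n_disc, 0.5)
        return float(min(p, 1.0))
    chi2 = (abs(n01 - n10) - 1.0) ** 2 / n_disc
    return float(stats.chi2.sf(chi2, df=1))


def cochran_q(decisions: pd.DataFrame) -> Tuple[float, int, float]:
    """Cochran's Q over >= 3 criteria columns; returns (Q, df, p).

    With identical columns Q = 0 and p = 1; with k = 2 the statistic reduces
    to McNemar's chi-square without continuity correction.
    """
    x = decisions.dropna().astype(int).to_numpy()
    n_sub, k = x.shape
    if k < 2:
        raise ValueError("Cochran's Q needs at least 2 criteria")
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - (row**2).sum()
    df = k - 1
    if denom == 0:
        return 0.0, df, 1.0
    q = (k - 1) * (k * (col**2).sum() - col.sum() ** 2) / denom
    return float(q), df, float(stats.chi2.sf(q, df=df))


def bayes_predictive_values(sensitivity_pct: float, specificity_pct: float,
                            n_patients: int, n_controls: int) -> Tuple[float, float]:
    """PPV/NPV implied by SN, SP and the arm sizes (count-based prevalence)."""
    sn = sensitivity_pct / 100.0
    sp = specificity_pct / 100.0
    tp = sn * n_patients
    fn = (1 - sn) * n_patients
    tn = sp * n_controls
    fp = (1 - sp) * n_controls
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = 100.0 * tn / (tn + fn) if tn + fn > 0 else float("nan")
    return ppv, npv


def criteria_table(decisions: pd.DataFrame, truth: pd.Series,
                   combinations: Optional[Dict[str, Tuple[List[str], int]]] = None
                   ) -> pd.DataFrame:
    """Diagnostic-performance table for single criteria and named combinations.

    ``combinations`` maps a row label to (constituent column names, k). The
    output mirrors the printed layout: one row per criterion with evaluable
    arm sizes and the five metrics (unrounded; display rounding is left to
    the caller).
    """
    rows = []

    def add(name: str, vec: pd.Series) -> None:
        s = summarize_criterion(vec, truth)
        rows.append({
            "criterion": name,
            "n_patients": s.n_patients, "n_controls": s.n_controls,
            "tp": s.tp, "fp": s.fp, "tn": s.tn, "fn": s.fn,
            "sensitivity": s.sensitivity, "specificity": s.specificity,
            "accuracy": s.accuracy, "ppv": s.ppv, "npv": s.npv,
        })

    for col in decisions.columns:
        add(col, decisions[col])
    for name, (cols, k) in (combinations or {}).items():
        add(name, combine_criteria(decisions[list(cols)], k))
    return pd.DataFrame(rows)
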