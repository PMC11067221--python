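"""Protein-centric CAFA evaluation metrics.

Fmax, IC-weighted Fmax, Smin, AUPRC, AUROC and coverage over a threshold
grid tau in (0, 1].  Precision at a threshold averages over the m(tau)
proteins with at least one call; recall averages over all test proteins.
Smin is the minimal Euclidean norm of (remaining uncertainty, misinformation)
in bits, with term weights given by conditional information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default CAFA threshold grid 0.01 .. 1.00
DEFAULT_TAUS = np.round(np.arange(1, 101) / 100.0, 2)


@dataclass
class EvalConfig:
    taus: np.ndarray = field(default_factory=lambda: DEFAULT_TAUS.copy())

    def __post_init__(self):
        self.taus = np.asarray(self.taus, dtype=float)
        if not np.all(np.diff(self.taus) > 0):
            raise ValueError("taus must be strictly increasing")


@dataclass
class PRCurve:
    taus: np.ndarray        # thresholds with at least one called protein
    precision: np.ndarray
    recall: np.ndarray
    m_tau: np.ndarray       # proteins with >=1 score >= tau


@dataclass
class MetricsReport:
    fmax: float
    tau_opt: float | None
    wfmax: float
    wtau_opt: float | None
    smin: float
    stau_opt: float | None
    auprc: float
    auroc: float | None
    coverage: float

    def as_dict(self) -> dict:
        return {
            "fmax": self.fmax, "tau_opt": self.tau_opt,
            "wfmax": self.wfmax, "wtau_opt": self.wtau_opt,
            "smin": self.smin, "stau_opt": self.stau_opt,
            "auprc": self.auprc, "auroc": self.auroc,
            "coverage": self.coverage,
        }


def _check(Y, S, ic=None):
    Y = np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs S {S.shape}")
    if ic is not None:
        ic = np.asarray(ic, dtype=float)
        if ic.shape != (Y.shape[1],):
            raise ValueError("ic length does not match term count")
        if (ic < 0).any():
            raise ValueError("ic must be non-negative")
    return Y, S, ic


def pr_curve(Y, S, cfg: EvalConfig | None = None,
             weights: np.ndarray | None = None) -> PRCurve:
    """Protein-centric (optionally IC-weighted) precision/recall per threshold.

    Precision at tau averages TP_i/pred_i over proteins with >=1 call;
    recall averages TP_i/true_i over *all* proteins, counting proteins with
    empty true sets as recall 1.  Thresholds where no protein is called are
    skipped.  With ``weights`` the counts become weighted sums.
    """
    cfg = cfg or EvalConfig()
    Y, S, _ = _check(Y, S)
    m = Y.shape[0]
    w = np.ones(Y.shape[1]) if weights is None else np.asarray(weights, float)
    true_w = Y @ w
    n_empty = int((true_w == 0).sum())
    if n_empty:
        logger.info("%d protein(s) with empty true sets count recall=1", n_empty)
    taus, prs, rcs, ms = [], [], [], []
    for tau in cfg.taus:
        called = S >= tau
        pred_w = called @ w
        tp_w = (called * Y) @ w
        has_call = pred_w > 0
        m_tau = int(has_call.sum())
        if m_tau == 0:
            continue
        pr = float(np.mean(tp_w[has_call] / pred_w[has_call]))
        rc_i = np.where(true_w > 0, tp_w / np.where(true_w > 0, true_w, 1.0), 1.0)
        rc = float(np.mean(rc_i))
        taus.append(tau); prs.append(pr); rcs.append(rc); ms.append(m_tau)
    return PRCurve(np.array(taus), np.array(prs), np.array(rcs),
                   np.array(ms, dtype=int))


def fmax(curve: PRCurve) -> tuple[float, float | None]:
    """Maximum harmonic mean of precision and recall over the grid."""
    best, best_tau = 0.0, None
    for tau, pr, rc in zip(curve.taus, curve.precision, curve.recall):
        if pr + rc == 0:
            continue
        f = 2 * pr * rc / (pr + rc)
        if f > best:
            best, best_tau = f, float(tau)
    return best, best_tau


def weighted_fmax(Y, S, ic, cfg: EvalConfig | None = None
                  ) -> tuple[float, float | None]:
    """Fmax with per-term information-content weights on TP/pred/true counts."""
    Y, S, ic = _check(Y, S, ic)
    return fmax(pr_curve(Y, S, cfg, weights=ic))


def smin(Y, S, ic, cfg: EvalConfig | None = None
         ) -> tuple[float, float | None]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the grid (bits).

    ru(tau): average per protein of the IC of true-but-unpredicted terms;
    mi(tau): average IC of predicted-but-untrue terms.  Unlike precision,
    every threshold participates (no calls simply means mi=0, ru=total IC).
    """
    cfg = cfg or EvalConfig()
    Y, S, ic = _check(Y, S, ic)
    m = Y.shape[0]
    best, best_tau = np.inf, None
    for tau in cfg.taus:
        called = S >= tau
        fn = (Y * ~called) @ ic
        fp = (called * (1 - Y)) @ ic
        ru = float(fn.sum()) / m
        mi = float(fp.sum()) / m
        s = float(np.hypot(ru, mi))
        if s < best:
            best, best_tau = s, float(tau)
    return best, best_tau


def auprc(curve: PRCurve) -> float:
    """Step-sum area under the protein-centric precision-recall curve.

    Recall decreases as tau rises, so the printed step sum
    sum_i pr(tau_i) (rc(tau_i) - rc(tau_{i-1})) is negative; its magnitude
    is reported.
    """
    if len(curve.taus) == 0:
        return 0.0
    # walk thresholds from highest to lowest; recall grows from the 0 anchor
    pr = curve.precision[::-1]
    rc = curve.recall[::-1]
    rc_prev = np.concatenate([[0.0], rc[:-1]])
    return float(np.sum(pr * (rc - rc_prev)))


def auroc(Y, S, cfg: EvalConfig | None = None) -> float | None:
    """Micro-averaged area under the ROC curve over all protein-term pairs.

    Computed as the exact rank statistic (probability that a random positive
    pair outscores a random negative pair, ties counted half), which the
    threshold step sum converges to.  Returns None when either class is
    absent.
    """
    Y, S, _ = _check(Y, S)
    y = Y.ravel().astype(bool)
    s = S.ravel()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    # rank-sum with midranks handles ties exactly
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum = float(ranks[y].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def coverage(S) -> float:
    """Fraction of proteins with at least one strictly positive score."""
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        return 0.0
    return float(np.mean((S > 0).any(axis=1)))


def evaluate(Y, S, ic=None, cfg: EvalConfig | None = None) -> MetricsReport:
    """Compute the full protein-centric metrics report."""
    cfg = cfg or EvalConfig()
    Y, S, ic = _check(Y, S, ic)
    curve = pr_curve(Y, S, cfg)
    f, tau = fmax(curve)
    if ic is not None:
        wf, wtau = weighted_fmax(Y, S, ic, cfg)
        s, stau = smin(Y, S, ic, cfg)
    else:
        wf, wtau, s, stau = float("nan"), None, float("nan"), None
    return MetricsReport(
        fmax=f, tau_opt=tau, wfmax=wf, wtau_opt=wtau, smin=s,
        stau_opt=stau, auprc=auprc(curve), auroc=auroc(Y, S, cfg),
        coverage=coverage(S),
    )
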