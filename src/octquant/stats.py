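"""Evaluation protocol: Dice conventions, frame-wise identification
metrics with exact binomial confidence intervals, Cohen's kappa,
ICC(2,1) absolute agreement, Bland–Altman bias, and consensus-frame
selection for external testing against two independent observers.

Dice is scored per frame and per class: true-positive frames carry the
pixel-overlap Dice, false-positive and false-negative frames score 0,
and true-negative frames carry no score and are excluded from all Dice
aggregation (they do enter confusion tables and kappa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Frame
from .errors import (
    DegenerateTableError,
    DomainError,
    EmptySetError,
    GeometryMismatchError,
    IndexMismatchError,
    LengthMismatchError,
    TooFewPairsError,
    UndefinedMetricError,
)


@dataclass(frozen=True)
class ConfusionTable:
    """Frame-wise 2x2 presence counts for one class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one frame")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class FrameDiceRecord:
    """Per-frame, per-class Dice with its presence-agreement category."""

    class_code: int
    frame_index: int
    dice: Optional[float]  # None for TN frames
    category: str  # TP | FP | FN | TN


@dataclass(frozen=True)
class AgreementResult:
    """Point estimate with a 95% confidence interval."""

    estimate: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n: int
    method: str


def dice_frame(ref: Frame, pred: Frame, class_code: int) -> FrameDiceRecord:
    """Per-frame Dice for one class with TP/FP/FN/TN categorisation."""
    if ref.geometry != pred.geometry:
        raise GeometryMismatchError("reference and prediction geometry differ")
    a = ref.labels == class_code
    b = pred.labels == class_code
    in_ref, in_pred = bool(a.any()), bool(b.any())
    idx = ref.frame_index
    if in_ref and in_pred:
        d = 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))
        return FrameDiceRecord(class_code, idx, float(d), "TP")
    if in_ref:
        return FrameDiceRecord(class_code, idx, 0.0, "FN")
    if in_pred:
        return FrameDiceRecord(class_code, idx, 0.0, "FP")
    return FrameDiceRecord(class_code, idx, None, "TN")


def aggregate_dice(records: Iterable[FrameDiceRecord], mode: str = "all") -> tuple[float, float]:
    """Mean ± SD of per-frame Dice.

    ``mode='all'`` averages over TP, FP and FN frames (TN frames carry no
    score); ``mode='tp_only'`` over true-positive frames only.
    """
    if mode not in ("all", "tp_only"):
        raise ValueError("mode must be 'all' or 'tp_only'")
    keep = ("TP",) if mode == "tp_only" else ("TP", "FP", "FN")
    vals = [r.dice for r in records if r.category in keep]
    if not vals:
        raise EmptySetError(f"no qualifying frames for mode={mode}")
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k/n."""
    if not (0 <= k <= n) or n < 1:
        raise DomainError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def _proportion(k: int, n: int, name: str) -> AgreementResult:
    if n == 0:
        raise UndefinedMetricError(f"{name} has a zero denominator")
    lo, hi = clopper_pearson(k, n)
    return AgreementResult(k / n, lo, hi, n, "clopper-pearson")


def binary_metrics(t: ConfusionTable) -> dict[str, AgreementResult]:
    """Accuracy, sensitivity, specificity, PPV and NPV with exact 95% CIs.

    All values are proportions in [0, 1]; a metric with a zero denominator
    raises UndefinedMetricError when accessed individually via
    ``_proportion`` — here it is simply omitted from the result.
    """
    out: dict[str, AgreementResult] = {}
    cells = {
        "accuracy": (t.tp + t.tn, t.n),
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
    }
    for name, (k, n) in cells.items():
        if n > 0:
            out[name] = _proportion(k, n, name)
    return out


def cohens_kappa(t: ConfusionTable) -> AgreementResult:
    """Chance-corrected agreement for a 2x2 frame-presence table.

    kappa = (po - pe) / (1 - pe) with po the observed and pe the expected
    agreement under marginal independence. The 95% CI is Wald, using the
    large-sample standard error of kappa (Fleiss, Cohen & Everitt form).
    """
    n = t.n
    po = (t.tp + t.tn) / n
    p1, q1 = (t.tp + t.fn) / n, (t.tp + t.fp) / n  # positive marginals
    p0, q0 = (t.fp + t.tn) / n, (t.fn + t.tn) / n  # negative marginals
    pe = p1 * q1 + p0 * q0
    if pe == 1.0:
        raise DegenerateTableError("expected agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt large-sample variance of kappa-hat
    cells = {  # (observed proportion, row marginal, col marginal)
        "tp": (t.tp / n, p1, q1),
        "fn": (t.fn / n, p1, q0),
        "fp": (t.fp / n, p0, q1),
        "tn": (t.tn / n, p0, q0),
    }
    a = sum(
        pij * (1.0 - (pi + qj) * (1.0 - kappa)) ** 2
        for key, (pij, pi, qj) in cells.items()
        if key in ("tp", "tn")
    )
    b = sum(
        pij * (pi + qj) ** 2
        for key, (pij, pi, qj) in cells.items()
        if key in ("fp", "fn")
    ) * (1.0 - kappa) ** 2
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / ((1.0 - pe) ** 2 * n)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(kappa, kappa - 1.96 * se, kappa + 1.96 * se, n, "kappa-wald")


def icc_absolute(x1: Sequence[float], x2: Sequence[float], level: float = 0.95) -> AgreementResult:
    """Single-measures ICC(2,1): two-way random effects, absolute agreement.

    Computed from the two-way ANOVA mean squares (subjects MSR, raters
    MSC, residual MSE); the confidence interval is the F-based interval of
    McGraw & Wong. Both subjects and raters are treated as random samples,
    so a systematic rater bias lowers the coefficient.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatchError("paired measurement vectors differ in length")
    n = a.size
    if n < 5 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise TooFewPairsError("need at least 5 finite pairs")
    k = 2
    data = np.stack([a, b], axis=1)  # n subjects x k raters
    grand = data.mean()
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_rater = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0

    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    if mse > 0 and icc < 1.0:
        # McGraw & Wong (1996) F-based interval for ICC(A,1)
        alpha = 1.0 - level
        a_ = (k * icc) / (n * (1.0 - icc))
        b_ = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f2 = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = float(
            n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = float(
            n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        )
    return AgreementResult(float(icc), ci_low, ci_high, n, "icc(2,1)")


def bland_altman(x1: Sequence[float], x2: Sequence[float]) -> dict[str, float]:
    """Bland–Altman bias and 95% limits of agreement.

    Differences are prediction minus reference (``x1 - x2`` with ``x1``
    the prediction); limits are mean ± 1.96 SD.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatchError("paired vectors differ in length")
    if a.size < 2:
        raise TooFewPairsError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": mean_diff - 1.96 * sd_diff,
        "loa_high": mean_diff + 1.96 * sd_diff,
    }


def consensus_frames(
    obs1: pd.Series, obs2: pd.Series
) -> pd.Series:
    """Frames on which two observers agree on presence/absence.

    ``obs1``/``obs2`` are boolean presence Series indexed by frame. The
    returned Series is restricted to agreeing frames and carries the
    shared call (the consensus label).
    """
    if not obs1.index.equals(obs2.index):
        if set(obs1.index) != set(obs2.index):
            raise IndexMismatchError("observer tables cover different frames")
        obs2 = obs2.reindex(obs1.index)
    agree = obs1.astype(bool) == obs2.astype(bool)
    return obs1[agree].astype(bool)


def mean_reference(obs1: Sequence[float], obs2: Sequence[float]) -> np.ndarray:
    """Element-wise mean of two observers' measurements (the reference)."""
    a = np.asarray(obs1, dtype=float)
    b = np.asarray(obs2, dtype=float)
    if a.shape != b.shape:
        raise LengthMismatchError("observer vectors differ in length")
    return (a + b) / 2.0


def confusion_from_presence(ref: Sequence[bool], pred: Sequence[bool]) -> ConfusionTable:
    """Build a frame-wise 2x2 table from paired presence calls."""
    r = np.asarray(ref, dtype=bool)
    p = np.asarray(pred, dtype=bool)
    if r.shape != p.shape:
        raise LengthMismatchError("presence vectors differ in length")
    return ConfusionTable(
        tp=int(np.count_nonzero(r & p)),
        fp=int(np.count_nonzero(~r & p)),
        fn=int(np.count_nonzero(r & ~p)),
        tn=int(np.count_nonzero(~r & ~p)),
    )
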