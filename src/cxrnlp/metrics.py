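"""Diagnostic-accuracy statistics for binary classifiers.

Implements the standard 2x2 contingency statistics used to audit a
screening classifier: sensitivity (recall), specificity, predictive
values, accuracy, F1, likelihood ratios, exact binomial confidence
intervals, and unweighted Cohen's kappa for inter-rater agreement.

Conventions
-----------
* Proportion metrics are stored on the [0, 1] scale; use
  :func:`percent` for the conventional x100 presentation with
  round-half-away-from-zero at one decimal.
* A metric whose denominator is zero is *not applicable* and is reported
  as ``None``, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy.stats import beta, norm

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "AgreementResult",
    "confusion",
    "metrics",
    "proportion_ci",
    "likelihood_ratio_ci",
    "cohens_kappa",
    "percent",
    "reconstruct_confusion",
]


def percent(x: Optional[float], decimals: int = 1) -> Optional[float]:
    """Scale a proportion to percent, rounding half away from zero.

    ``percent(0.935) == 93.5``; ``None`` (not-applicable) passes through.
    Decimal-based rounding avoids both binary-float surprises and
    banker's rounding.
    """
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of predicted vs reference labels (positives first)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Reference-positive count (tp + fn)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Reference-negative count (fp + tn)."""
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Derived diagnostic statistics with per-metric confidence intervals.

    Proportions live on [0, 1]; ``f1`` is the harmonic mean of ppv and
    sensitivity. ``ci`` maps metric name to a (lo, hi) tuple at
    ``ci_level``. ``not_applicable`` lists metrics whose denominator was
    zero; their values are None. ``continuity_corrected`` flags
    likelihood ratios computed after a 0.5 zero-cell correction.
    """

    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    ci_level: float
    ci: dict = field(default_factory=dict)
    not_applicable: frozenset = frozenset()
    continuity_corrected: frozenset = frozenset()

    def as_row(self) -> dict:
        """Flatten to a percent-scaled mapping in report-table order."""
        row: dict = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            row[name] = percent(value)
            lo, hi = self.ci.get(name, (None, None))
            row[f"{name}_lo"], row[f"{name}_hi"] = percent(lo), percent(hi)
        for name in ("lr_pos", "lr_neg"):
            value = getattr(self, name)
            row[name] = None if value is None else round(value, 2)
            lo, hi = self.ci.get(name, (None, None))
            row[f"{name}_lo"] = None if lo is None else round(lo, 2)
            row[f"{name}_hi"] = None if hi is None else round(hi, 2)
        row["accuracy"] = percent(self.accuracy)
        row["f1"] = percent(self.f1)
        return row


@dataclass(frozen=True)
class AgreementResult:
    """Unweighted Cohen's kappa with its ingredients."""

    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float
    n: int
    undefined: bool = False


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Tabulate predicted vs reference binary labels into a 2x2 matrix."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"pred and truth must be equal-length 1-D vectors, got shapes {p.shape} and {t.shape}")
    if p.size == 0:
        raise ValueError("empty label vectors")
    for name, v in (("pred", p), ("truth", t)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def proportion_ci(k: int, n: int, level: float = 0.95, method: str = "clopper-pearson") -> tuple[float, float]:
    """Two-sided confidence interval for a binomial proportion.

    Default is the exact Clopper-Pearson interval (beta quantiles); the
    Wilson score interval is available via ``method="wilson"``. The
    interval always brackets k/n; lo is exactly 0 when k=0 and hi is
    exactly 1 when k=n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
        return lo, hi
    if method == "wilson":
        z = float(norm.ppf(1 - alpha / 2))
        phat = k / n
        denom = 1 + z * z / n
        centre = phat + z * z / (2 * n)
        half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
        return (centre - half) / denom, (centre + half) / denom
    raise ValueError(f"unknown CI method {method!r}")


def likelihood_ratio_ci(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """Log-method confidence intervals for LR+ and LR-.

    ``exp(log LR +/- z * SE)`` with ``SE = sqrt(1/tp - 1/(tp+fn) + 1/fp -
    1/(fp+tn))`` for LR+ and the mirrored expression for LR-. Any zero
    cell entering a ratio triggers a documented 0.5 continuity correction
    on all four cells, flagged in the result.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = float(norm.ppf(1 - (1 - level) / 2))
    out: dict = {"corrected": set()}

    def _one(num_k: int, num_n: int, den_k: int, den_n: int, name: str) -> None:
        # LR = (num_k/num_n) / (den_k/den_n); zero num_k or den_k breaks the log scale
        corrected = num_k == 0 or den_k == 0 or num_k == num_n or den_k == den_n
        if corrected:
            a, b, c, d = num_k + 0.5, num_n + 1.0, den_k + 0.5, den_n + 1.0
            out["corrected"].add(name)
        else:
            a, b, c, d = float(num_k), float(num_n), float(den_k), float(den_n)
        lr = (a / b) / (c / d)
        se = math.sqrt(1 / a - 1 / b + 1 / c - 1 / d)
        out[name] = lr
        out[f"{name}_ci"] = (lr * math.exp(-z * se), lr * math.exp(z * se))

    # LR+ = sens / (1 - spec): numerator tp/(tp+fn), denominator fp/(fp+tn)
    _one(cm.tp, cm.positives, cm.fp, cm.negatives, "lr_pos")
    # LR- = (1 - sens) / spec: numerator fn/(tp+fn), denominator tn/(fp+tn)
    _one(cm.fn, cm.positives, cm.tn, cm.negatives, "lr_neg")
    return out


def metrics(cm: ConfusionMatrix, ci_level: float = 0.95, ci_method: str = "clopper-pearson") -> MetricSet:
    """Full diagnostic-accuracy panel from a 2x2 matrix.

    accuracy = (TP+TN)/(TP+TN+FP+FN); F1 = 2*PPV*sens/(PPV+sens), computed
    in the equivalent zero-safe form 2TP/(2TP+FP+FN). Proportion CIs use
    ``ci_method``; likelihood-ratio CIs use the log method.
    """
    na: set[str] = set()
    values: dict[str, Optional[float]] = {}
    cis: dict[str, tuple[float, float]] = {}

    def _prop(name: str, k: int, n: int) -> None:
        if n == 0:
            values[name] = None
            na.add(name)
            return
        values[name] = k / n
        cis[name] = proportion_ci(k, n, ci_level, ci_method)

    _prop("sensitivity", cm.tp, cm.positives)
    _prop("specificity", cm.tn, cm.negatives)
    _prop("ppv", cm.tp, cm.tp + cm.fp)
    _prop("npv", cm.tn, cm.tn + cm.fn)
    _prop("accuracy", cm.tp + cm.tn, cm.total)

    f1_denom = 2 * cm.tp + cm.fp + cm.fn
    if f1_denom == 0:
        values["f1"] = None
        na.add("f1")
    else:
        values["f1"] = 2 * cm.tp / f1_denom

    corrected: set[str] = set()
    sens, spec = values["sensitivity"], values["specificity"]
    if sens is None or spec is None:
        values["lr_pos"] = values["lr_neg"] = None
        na.update({"lr_pos", "lr_neg"})
    else:
        lr = likelihood_ratio_ci(cm, ci_level)
        corrected = lr["corrected"]
        values["lr_pos"] = sens / (1 - spec) if spec < 1 else lr["lr_pos"]
        values["lr_neg"] = (1 - sens) / spec if spec > 0 else lr["lr_neg"]
        cis["lr_pos"] = lr["lr_pos_ci"]
        cis["lr_neg"] = lr["lr_neg_ci"]

    return MetricSet(
        cm=cm,
        sensitivity=values["sensitivity"],
        specificity=values["specificity"],
        ppv=values["ppv"],
        npv=values["npv"],
        accuracy=values["accuracy"],
        f1=values["f1"],
        lr_pos=values["lr_pos"],
        lr_neg=values["lr_neg"],
        ci_level=ci_level,
        ci=cis,
        not_applicable=frozenset(na),
        continuity_corrected=frozenset(corrected),
    )


def cohens_kappa(r1: Sequence[int], r2: Sequence[int]) -> AgreementResult:
    """Unweighted Cohen's kappa between two binary raters.

    kappa = (po - pe) / (1 - pe), where po is the observed agreement
    proportion and pe the chance agreement from the rater marginals.
    When both raters are constant and identical (pe = 1), kappa is
    undefined and flagged rather than forced to a number.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("raters must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rated items")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("ratings must be binary 0/1")
    po = float(np.mean(a == b))
    p1a, p1b = float(np.mean(a)), float(np.mean(b))
    pe = p1a * p1b + (1 - p1a) * (1 - p1b)
    if pe >= 1.0:
        return AgreementResult(kappa=None, observed_agreement=po, expected_agreement=pe, n=n, undefined=True)
    return AgreementResult(
        kappa=(po - pe) / (1 - pe),
        observed_agreement=po,
        expected_agreement=pe,
        n=n,
    )


def reconstruct_confusion(
    n: int,
    n_pos: int,
    sensitivity_pct: float,
    specificity_pct: float,
    ppv_pct: float,
    npv_pct: Optional[float] = None,
    f1_pct: Optional[float] = None,
) -> ConfusionMatrix:
    """Recover the integer 2x2 matrix behind rounded published marginals.

    Enumerates all (tp, fp) with tp <= n_pos and fp <= n - n_pos and keeps
    matrices whose percent-scale sensitivity, specificity, PPV (and NPV /
    F1 when supplied) round to the quoted one-decimal values. Exactly one
    candidate must survive; ambiguity or an empty candidate set raises.
    """
    n_neg = n - n_pos
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos must be in [0, n]")
    candidates = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        if percent(tp / n_pos) != sensitivity_pct:
            continue
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            if percent(tn / n_neg) != specificity_pct:
                continue
            if tp + fp == 0 or percent(tp / (tp + fp)) != ppv_pct:
                continue
            if npv_pct is not None:
                if tn + fn == 0 or percent(tn / (tn + fn)) != npv_pct:
                    continue
            if f1_pct is not None:
                if percent(2 * tp / (2 * tp + fp + fn)) != f1_pct:
                    continue
            candidates.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    if not candidates:
        raise ValueError("no integer confusion matrix is consistent with the quoted marginals")
    if len(candidates) > 1:
        raise ValueError(f"marginals are ambiguous: {len(candidates)} consistent matrices found")
    return candidates[0]
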