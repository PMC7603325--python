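"""Evaluation statistics for triggered video collection.

Window-level precision/recall/F-measure treat the *presence of video* as
the classifier output for each 1-s window, compared against a full
labelling of the low-cost sensor stream.  Video-level precision is simply
the fraction of collected videos containing the target behaviour.  Methods
are compared with a two-sided Fisher's exact test on the 2×2 table of
(target, non-target) video counts, reporting the conditional maximum
likelihood odds ratio and its exact (central) confidence interval — the
convention of R's ``fisher.test`` / the ``exact2x2`` package.

Two conditional-MLE conventions are provided. The default, ``reference``,
is a faithful port of the root-finding procedure used by the reference R
implementation (Brent's *zeroin* at tolerance ``eps**0.25`` on a
reciprocal noncentrality scale) and reproduces its published estimates
digit for digit.  ``tight`` solves the conditional score equation
E_ψ[a | margins] = a to relative tolerance 1e-12; the two agree to about
four significant digits, the difference being purely the reference
solver's stopping rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Video-outcome counts: rows = method, columns = (target, non-target)."""

    a: int  # proposed method, target videos
    b: int  # proposed method, non-target videos
    c: int  # naive method, target videos
    d: int  # naive method, non-target videos

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("at least one count must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class WindowMetrics:
    precision: float
    recall: float
    f_measure: float

    def rounded(self, ndigits: int = 2) -> "WindowMetrics":
        return WindowMetrics(round(self.precision, ndigits),
                             round(self.recall, ndigits),
                             round(self.f_measure, ndigits))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_counts(predicted_positive, truth, target: str):
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValidationError("prediction and label streams disagree in length")
    pos = truth == target
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, fn


def window_metrics(log_or_flags, truth=None, target: str = "foraging") -> WindowMetrics:
    """Window-level precision/recall/F with camera presence as the output.

    ``log_or_flags`` may be a :class:`~aioa.triggers.DeploymentLog` (its
    per-window camera flag and, if ``truth`` is None, its stored labels are
    used) or a boolean per-window array.  Zero denominators yield 0.
    """
    from .triggers import DeploymentLog

    if isinstance(log_or_flags, DeploymentLog):
        flags = log_or_flags.camera_on
        if truth is None:
            truth = log_or_flags.truth
    else:
        flags = log_or_flags
    if truth is None:
        raise ValidationError("window truth labels are required")
    tp, fp, fn = confusion_counts(flags, truth, target)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return WindowMetrics(precision, recall, f_measure(precision, recall))


def video_precision(target_count: int, total_count: int) -> float:
    """Fraction of collected videos that contain the target behaviour."""
    if total_count <= 0:
        raise ValidationError("total video count must be > 0")
    if not (0 <= target_count <= total_count):
        raise ValidationError("target count must be within [0, total]")
    return target_count / total_count


def videos_containing_target(log, target: str) -> tuple[int, int]:
    """(videos containing >= 1 target-labelled window, total videos)."""
    if log.truth is None:
        raise ValidationError("deployment log carries no truth labels")
    total = len(log.camera_events)
    hit = 0
    for _, s, e in log.camera_events:
        i0 = int(math.floor(s / log.window_s))
        i1 = int(math.ceil(e / log.window_s))
        if np.any(log.truth[i0:i1] == target):
            hit += 1
    return hit, total


# ---------------------------------------------------------------------------
# Fisher's exact test with conditional-MLE odds ratio


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _support_and_logbinom(n1, n2, m1):
    lo, hi = max(0, m1 - n2), min(n1, m1)
    xs = np.arange(lo, hi + 1)
    return lo, hi, xs, _log_binom(n1, xs) + _log_binom(n2, m1 - xs)


def _conditional_mean(log_psi, xs, lb):
    w = lb + xs * log_psi
    w = np.exp(w - w.max())
    return float((xs * w).sum() / w.sum())


def conditional_mle_or(a: int, b: int, c: int, d: int,
                       convention: str = "reference") -> float:
    """Conditional MLE of the odds ratio given both table margins.

    The estimate is the noncentrality ψ of Fisher's noncentral
    hypergeometric distribution for which the expected first cell equals
    the observed ``a``.  ``convention="reference"`` reproduces the R
    ``fisher.test`` solver (see module docstring); ``"tight"`` solves the
    same equation to relative tolerance 1e-12.  Degenerate tables return 0
    or ``inf`` when ``a`` sits on the support boundary.
    """
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi, xs, lb = _support_and_logbinom(n1, n2, m1)
    if lo == hi:
        return float("nan")  # margins fix the table; OR not identifiable
    if a == lo:
        return 0.0
    if a == hi:
        return float("inf")

    if convention == "tight":
        root = brentq(lambda lp: _conditional_mean(lp, xs, lb) - a,
                      -60.0, 60.0, xtol=1e-13, rtol=1e-14)
        return float(math.exp(root))
    if convention != "reference":
        raise ValidationError(f"unknown OR convention {convention!r}")

    tol = np.finfo(float).eps ** 0.25
    mu1 = _conditional_mean(0.0, xs, lb)

    def mean_psi(psi):
        return _conditional_mean(math.log(psi), xs, lb)

    if mu1 > a:  # root in (0, 1)
        return _zeroin(lambda t: mean_psi(t) - a, 1e-300, 1.0, tol)
    if mu1 < a:  # solve on the reciprocal scale, as the reference does
        t = _zeroin(lambda t: mean_psi(1.0 / t) - a, np.finfo(float).eps, 1.0, tol)
        return 1.0 / t
    return 1.0


def _zeroin(f, ax, bx, tol, maxit=1000):
    """Brent's zeroin exactly as in the reference implementation."""
    eps = np.finfo(float).eps
    a, b = ax, bx
    fa, fb = f(a), f(b)
    c, fc = a, fa
    while maxit:
        prev_step = b - a
        if abs(fc) < abs(fb):
            a, b, c = b, c, b
            fa, fb, fc = fb, fc, fb
        tol_act = 2 * eps * abs(b) + tol / 2
        new_step = (c - b) / 2
        if abs(new_step) <= tol_act or fb == 0.0:
            return b
        if abs(prev_step) >= tol_act and abs(fa) > abs(fb):
            cb = c - b
            if a == c:
                t1 = fb / fa
                p = cb * t1
                q = 1.0 - t1
            else:
                q = fa / fc
                t1 = fb / fc
                t2 = fb / fa
                p = t2 * (cb * q * (q - t1) - (b - a) * (t1 - 1.0))
                q = (q - 1.0) * (t1 - 1.0) * (t2 - 1.0)
            if p > 0:
                q = -q
            else:
                p = -p
            if p < (0.75 * cb * q - abs(tol_act * q) / 2) and p < abs(prev_step * q / 2):
                new_step = p / q
        if abs(new_step) < tol_act:
            new_step = tol_act if new_step > 0 else -tol_act
        a, fa = b, fb
        b += new_step
        fb = f(b)
        if (fb > 0) == (fc > 0):
            c, fc = a, fa
        maxit -= 1
    return b


@dataclass
class FisherExactResult:
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_method: str
    or_convention: str

    def __iter__(self):
        return iter((self.p_value, self.odds_ratio, (self.ci_low, self.ci_high)))


def fisher_exact(table, p_method: str = "minlike",
                 or_convention: str = "reference",
                 confidence_level: float = 0.95) -> FisherExactResult:
    """Two-sided Fisher's exact test on a 2×2 video-count table.

    ``p_method="minlike"`` sums null hypergeometric probabilities no larger
    than the observed table's (the classic two-sided rule);
    ``"central"`` doubles the smaller one-sided tail (capped at 1).  The
    confidence interval inverts the exact conditional test (central).
    Degenerate margins make the odds ratio unidentifiable; it is reported
    as NaN with a unit-wide p of 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        table = ContingencyTable2x2(*[int(v) for v in arr.ravel()])
    a, b, c, d = table.a, table.b, table.c, table.d
    arr = table.as_array()
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if p_method == "minlike":
        p = float(scipy.stats.fisher_exact(arr, alternative="two-sided").pvalue)
    elif p_method == "central":
        p_less = float(scipy.stats.fisher_exact(arr, alternative="less").pvalue)
        p_greater = float(scipy.stats.fisher_exact(arr, alternative="greater").pvalue)
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValidationError(f"unknown p-value method {p_method!r}")
    if degenerate:
        return FisherExactResult(p, float("nan"), float("nan"), float("nan"),
                                 p_method, or_convention)
    orr = conditional_mle_or(a, b, c, d, convention=or_convention)
    ci = _scipy_odds_ratio(arr, kind="conditional").confidence_interval(
        confidence_level=confidence_level)
    return FisherExactResult(p, orr, float(ci.low), float(ci.high),
                             p_method, or_convention)
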