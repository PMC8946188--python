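"""Inferential statistics for clinical 2x2 tables and covariates.

Fisher's exact test (two-sided, sum of tables no more likely than the
observed one, margins fixed), the Wilcoxon rank-sum test, and the
univariate-to-multivariate logistic-regression workflow in which only
predictors with univariate p < 0.300 enter the multivariate model.

The Fisher p-value is computed by complete hypergeometric enumeration in
exact integer arithmetic, so tie decisions at equal table probabilities are
deterministic.  Logistic fits are unpenalized maximum likelihood; complete
separation (a zero cell for a binary predictor) is reported as a degenerate
fit (odds ratio near 0 or infinity, Wald p near 1) with ``separation_flag``
set, rather than silently switching to a penalized estimator.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError

log = logging.getLogger(__name__)

#: univariate p-value ceiling for entry into the multivariate model
DEFAULT_SCREEN_P = 0.300

#: |log-odds| beyond which a fit is treated as separated/degenerate
_SEPARATION_COEF = 12.0


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table; rows = exposure, columns = outcome yes/no.

    Layout::

                    outcome+  outcome-
        exposed        a         b
        unexposed      c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"table cells must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValidationError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Sample cross-product odds ratio a*d / (b*c)."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    @property
    def exposed_rate(self) -> float:
        """Outcome rate in the exposed row, a / (a + b)."""
        return self.a / (self.a + self.b)

    @property
    def unexposed_rate(self) -> float:
        return self.c / (self.c + self.d)

    @classmethod
    def from_vectors(cls, outcome: Sequence, exposure: Sequence) -> "TwoByTwo":
        o = np.asarray(outcome).astype(bool)
        e = np.asarray(exposure).astype(bool)
        if o.shape != e.shape:
            raise ValidationError("outcome and exposure must have the same length")
        return cls(
            a=int(np.sum(e & o)),
            b=int(np.sum(e & ~o)),
            c=int(np.sum(~e & o)),
            d=int(np.sum(~e & ~o)),
        )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float


def fisher_exact(table: TwoByTwo) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value is the sum, over all tables with the observed margins, of
    hypergeometric probabilities not exceeding that of the observed table.
    Probabilities are compared as exact integers (the common denominator
    C(n, c1) cancels), so no floating-point tie ambiguity arises.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = table.total
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = math.comb(r1, table.a) * math.comb(r2, c1 - table.a)
    numerator = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= w_obs:
            numerator += w
    p = float(Fraction(numerator, math.comb(n, c1)))
    return FisherResult(odds_ratio=table.odds_ratio, p_value=min(1.0, p))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the combined sample size is at
    most 30 and there are no ties; otherwise the normal approximation with
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 30 and not has_ties) else "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(1.0, res.pvalue))


def dichotomize(values: Sequence[float], cutpoint: float) -> np.ndarray:
    """Binary indicator 1 iff value >= cutpoint (e.g. median splits)."""
    return (np.asarray(values, dtype=float) >= cutpoint).astype(int)


@dataclass(frozen=True)
class LogisticResult:
    """One predictor's odds ratio and Wald p-value from a logistic fit."""

    predictor: str
    odds_ratio: float
    p_value: float
    included_in_multivariate: bool
    separation_flag: bool


@dataclass(frozen=True)
class ScreenedModel:
    """Univariate results plus the multivariate fit over screened predictors."""

    univariate: tuple[LogisticResult, ...]
    multivariate: tuple[LogisticResult, ...]
    screen_p: float


def _fit_logit(outcome: np.ndarray, design: pd.DataFrame):
    import statsmodels.api as sm

    X = sm.add_constant(design, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(outcome, X, family=sm.families.Binomial())
        return model.fit(maxiter=100)


def _check_outcome(outcome: np.ndarray) -> np.ndarray:
    outcome = np.asarray(outcome).astype(int)
    if set(np.unique(outcome)) - {0, 1}:
        raise ValidationError("outcome must be binary (0/1)")
    if outcome.min() == outcome.max():
        raise ValidationError("outcome must contain both classes")
    return outcome


def _is_separated(outcome: np.ndarray, predictor: np.ndarray, coef: float) -> bool:
    values = np.unique(predictor)
    if values.size == 2:
        table = TwoByTwo.from_vectors(outcome, predictor == values.max())
        if 0 in (table.a, table.b, table.c, table.d):
            return True
    return abs(coef) > _SEPARATION_COEF


def logistic_univariate(
    outcome: Sequence,
    predictor: Sequence,
    name: str = "predictor",
    screen_p: float = DEFAULT_SCREEN_P,
) -> LogisticResult:
    """Univariate logistic regression of a binary outcome on one predictor.

    For a binary predictor with all four cells non-zero the fitted odds
    ratio equals the table cross-product ratio.  ``included_in_multivariate``
    records whether the Wald p-value falls below ``screen_p``.
    """
    outcome = _check_outcome(outcome)
    pred = np.asarray(predictor, dtype=float)
    res = _fit_logit(outcome, pd.DataFrame({name: pred}))
    coef = float(res.params.iloc[1])
    p = float(res.pvalues.iloc[1])
    return LogisticResult(
        predictor=name,
        odds_ratio=float(np.exp(coef)),
        p_value=p,
        included_in_multivariate=p < screen_p,
        separation_flag=_is_separated(outcome, pred, coef),
    )


def multivariate_screen_and_fit(
    outcome: Sequence,
    predictors: pd.DataFrame,
    screen_p: float = DEFAULT_SCREEN_P,
) -> ScreenedModel:
    """Univariate screening followed by a multivariate logistic fit.

    Every predictor is first fitted univariately; those with univariate
    p < ``screen_p`` enter a joint multivariate model.  If no predictor
    passes, only the univariate results are returned (with a logged note).
    """
    outcome = _check_outcome(outcome)
    uni = tuple(
        logistic_univariate(outcome, predictors[col], name=str(col), screen_p=screen_p)
        for col in predictors.columns
    )
    screened = [r.predictor for r in uni if r.included_in_multivariate]
    if not screened:
        log.info("no predictor passed the p < %.3f screen; multivariate model skipped", screen_p)
        return ScreenedModel(univariate=uni, multivariate=(), screen_p=screen_p)
    design = predictors[screened].astype(float)
    res = _fit_logit(outcome, design)
    multi = []
    for col in screened:
        coef = float(res.params[col])
        multi.append(
            LogisticResult(
                predictor=col,
                odds_ratio=float(np.exp(coef)),
                p_value=float(res.pvalues[col]),
                included_in_multivariate=True,
                separation_flag=_is_separated(
                    outcome, design[col].to_numpy(), coef
                ),
            )
        )
    return ScreenedModel(univariate=uni, multivariate=tuple(multi), screen_p=screen_p)
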