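"""Cohort-level statistics for the figure-ground test battery.

Pearson correlations with Fisher-z confidence intervals, the test-retest
noise ceiling, hierarchical/stepwise regression with r-squared-change
partial-F tests, partial correlations, comparison of independent
correlations, paired t-tests with Cohen's dz, and audiogram screening.

Correlations are reported without multiple-comparison correction; p-values
are two-tailed throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionStep",
    "DegenerateDataError",
    "CollinearityError",
    "screen_audiogram",
    "AUDIOGRAM_FREQS_HZ",
    "pearson",
    "fisher_confidence_interval",
    "variance_explained_percent",
    "noise_ceiling",
    "hierarchical_regression",
    "stepwise_forward",
    "partial_correlation",
    "compare_independent_correlations",
    "paired_t_dz",
]

AUDIOGRAM_FREQS_HZ = (250, 500, 1000, 2000, 4000, 8000)


class DegenerateDataError(ValueError):
    """Zero-variance input makes the requested statistic undefined."""


class CollinearityError(ValueError):
    """Singular design matrix in a regression."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    ci95: tuple[float, float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "p": self.p,
                "ci95": [self.ci95[0], self.ci95[1]]}


@dataclass(frozen=True)
class RegressionStep:
    variables: tuple[str, ...]
    r: float
    r2: float
    r2_change: float
    f_change: float
    p_change: float

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables), "r": self.r, "r2": self.r2,
            "r2_change": self.r2_change, "f_change": self.f_change,
            "p_change": self.p_change,
        }


# ---------------------------------------------------------------------------
# Audiogram screening
# ---------------------------------------------------------------------------

def screen_audiogram(
    left: Sequence[float], right: Sequence[float]
) -> tuple[bool, float]:
    """Apply the mild-hearing-loss exclusion and compute the high-frequency
    average.

    Returns ``(include, hf_avg)``: a participant is excluded when the
    six-frequency (0.25-8 kHz) average is >= 20 dB HL in either ear;
    ``hf_avg`` is the mean of the four 4- and 8-kHz thresholds across ears.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != (6,) or right.shape != (6,):
        raise ValueError(
            f"expected thresholds at the 6 octave frequencies {AUDIOGRAM_FREQS_HZ}"
        )
    include = left.mean() < 20.0 and right.mean() < 20.0
    hf_avg = float(np.mean([left[4], left[5], right[4], right[5]]))
    return include, hf_avg


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def fisher_confidence_interval(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + conf / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed t-test p-value and a 95%
    Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero-variance column: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return CorrelationResult(r=r, n=n, p=0.0, ci95=(r, r), degenerate=True)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p, ci95=fisher_confidence_interval(r, n))


def variance_explained_percent(r: float) -> int:
    """Variance explained by a correlation, as an integer percentage of r**2."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return int(round(100 * r * r))


def noise_ceiling(block1: Sequence[float], block2: Sequence[float]) -> dict:
    """Test-retest noise ceiling of a measure: the correlation between the
    two blocks, its 95% CI (the plotted ceiling band), and the implied bound
    on explainable variance (r**2)."""
    res = pearson(block1, block2)
    return {
        "correlation": res,
        "ceiling_band": res.ci95,
        "explainable_variance": res.r ** 2,
    }


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """R-squared of an OLS fit with intercept; returns (r2, rank of design)."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise DegenerateDataError("zero-variance outcome")
    return 1.0 - float(np.sum(resid**2)) / tss, rank


def hierarchical_regression(
    y: Sequence[float],
    blocks: Sequence[tuple[Sequence[str], np.ndarray]],
) -> list[RegressionStep]:
    """Hierarchical OLS: predictors added block by block.

    ``blocks`` is an ordered sequence of ``(names, columns)`` where
    ``columns`` is an (n, k) array.  Each step reports the multiple r, r2,
    the r2 change over the previous step, and the partial-F test of that
    change.  Exactly collinear additions yield r2_change = 0 with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    steps: list[RegressionStep] = []
    X = np.empty((n, 0))
    names: tuple[str, ...] = ()
    r2_prev = 0.0
    rank_prev = 1
    for block_names, cols in blocks:
        cols = np.asarray(cols, dtype=float)
        if cols.ndim == 1:
            cols = cols[:, None]
        if cols.shape[0] != n:
            raise ValueError("predictor block length does not match outcome")
        X = np.column_stack([X, cols])
        names = names + tuple(block_names)
        if n <= X.shape[1] + 1:
            raise ValueError("more predictors than the sample can support")
        r2, rank = _r2(y, X)
        q = rank - rank_prev  # effective parameters added
        df2 = n - rank
        if q == 0:
            warnings.warn(
                f"block {tuple(block_names)} is collinear with earlier predictors",
                stacklevel=2,
            )
            f_change, p_change = 0.0, 1.0
            r2 = r2_prev
        else:
            f_change = ((r2 - r2_prev) / q) / ((1 - r2) / df2) if r2 < 1 else np.inf
            p_change = float(sps.f.sf(f_change, q, df2))
        steps.append(
            RegressionStep(
                variables=names,
                r=float(np.sqrt(max(r2, 0.0))),
                r2=float(r2),
                r2_change=float(r2 - r2_prev),
                f_change=float(f_change),
                p_change=p_change,
            )
        )
        r2_prev, rank_prev = r2, rank
    return steps


def stepwise_forward(
    y: Sequence[float],
    candidates: dict[str, Sequence[float]],
    entry_p: float = 0.05,
) -> dict:
    """Forward stepwise selection on the partial-F entry test.

    At each round the candidate with the smallest change-p below ``entry_p``
    enters; selection stops when no candidate qualifies.  Returns the path
    of :class:`RegressionStep` plus the never-entered variables.
    """
    y = np.asarray(y, dtype=float)
    remaining = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    entered: list[tuple[tuple[str], np.ndarray]] = []
    path: list[RegressionStep] = []
    while remaining:
        trials = []
        for name, col in remaining.items():
            steps = hierarchical_regression(y, entered + [((name,), col)])
            trials.append((steps[-1].p_change, name, steps[-1]))
        trials.sort(key=lambda t: (t[0], t[1]))
        p_best, name_best, step_best = trials[0]
        if p_best >= entry_p:
            break
        entered.append(((name_best,), remaining.pop(name_best)))
        path.append(step_best)
    return {"path": path, "excluded": sorted(remaining)}


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray,
) -> CorrelationResult:
    """Pearson correlation of x and y after partialling out the covariates.

    Both variables are residualised on the covariates (with intercept); the
    residual correlation is tested on n - k - 2 degrees of freedom and its
    Fisher CI uses an effective sample size of n - k.  A zero-variance
    residual returns r = 0 with a warning (flagged degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if x.size != n or y.size != n:
        raise ValueError("covariates must match x and y in length")
    if n <= k + 3:
        raise ValueError("too few observations for the requested covariates")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # residuals that are numerically zero (variable fully explained by the
    # covariates) leave the partial correlation undefined
    if rx.std() <= 1e-10 * max(x.std(), 1.0) or ry.std() <= 1e-10 * max(y.std(), 1.0):
        warnings.warn("zero-variance residual: partial correlation set to 0", stacklevel=2)
        return CorrelationResult(r=0.0, n=n, p=1.0, ci95=(np.nan, np.nan), degenerate=True)
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, p=0.0, ci95=(r, r), degenerate=True)
    t = r * np.sqrt(df / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, p=p, ci95=fisher_confidence_interval(r, n - k))


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher-z comparison of two correlations from independent samples.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-tailed normal p-value.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p


def paired_t_dz(a: Sequence[float], b: Sequence[float]) -> dict:
    """Paired-samples t-test with Cohen's dz effect size.

    dz = mean(a - b) / sd(a - b); df = n - 1.  Constant differences (zero
    variance) make the test degenerate and raise an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two paired 1-D samples with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences: paired t undefined")
    n = diff.size
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return {"t": t, "df": n - 1, "p": p, "dz": float(diff.mean() / sd), "n": n}
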