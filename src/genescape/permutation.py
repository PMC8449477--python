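"""Scrambled-order null distributions and exceedance statistics.

Smoothing correlates neighboring windows, so "how low can a window mean get
by chance" is answered empirically: scramble the gene order — equivalently,
draw random sets of window-size genes — and record each set's mean. The
empirical distribution of those means yields thresholds at a chosen tail
probability (alpha = 0.001 with 1000 sets: the minimum/maximum null mean),
and an expected count of threshold-crossing windows under random sampling
with replacement.

The binomial tail probability reported by :func:`exceedance_stats` treats
windows as independent draws, matching the random-sampling assumption; the
windows of a real landscape overlap, so the null calibrates the marginal
crossing rate, not joint independence (the count is overdispersed — see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, UndefinedValueError
from .landscape import LandscapeTrack


@dataclass
class NullModel:
    """Empirical null of window means from random gene sets."""

    statistic: str
    null_values: np.ndarray
    alpha: float
    seed: int
    n_sets: int
    set_size: int
    threshold_low: float = field(init=False)
    threshold_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_sets:
            raise ConfigError("null_values length must equal n_sets")
        self.threshold_low = float(np.quantile(self.null_values, self.alpha, method="lower"))
        self.threshold_high = float(
            np.quantile(self.null_values, 1.0 - self.alpha, method="higher")
        )

    def as_metadata(self) -> dict:
        return {
            "statistic": self.statistic,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
        }


@dataclass
class ExceedanceReport:
    """Observed vs expected threshold-crossing window counts."""

    statistic: str
    direction: str
    threshold: float
    n_windows: int
    observed_count: int
    p_hat: float
    expected_count: float
    p_value: float

    def as_metadata(self) -> dict:
        return {
            "statistic": self.statistic,
            "direction": self.direction,
            "threshold": self.threshold,
            "n_windows": self.n_windows,
            "observed_count": self.observed_count,
            "p_hat": self.p_hat,
            "expected_count": self.expected_count,
            "p_value": self.p_value,
        }


def null_distribution(
    raw,
    set_size: int = 101,
    n_sets: int = 1000,
    seed: int = 0,
    alpha: float = 0.001,
    statistic: str = "",
) -> NullModel:
    """Means of ``n_sets`` random gene sets drawn from the non-missing values.

    Each set is drawn without replacement (a random set of distinct genes);
    sets are independent of each other. Deterministic for a fixed seed.
    """
    values = np.asarray(raw, dtype=float)
    values = values[np.isfinite(values)]
    if set_size > len(values):
        raise ConfigError(
            f"set_size {set_size} exceeds the {len(values)} available non-missing values"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(n_sets)
    for i in range(n_sets):
        means[i] = rng.choice(values, size=set_size, replace=False).mean()
    return NullModel(
        statistic=statistic,
        null_values=means,
        alpha=alpha,
        seed=seed,
        n_sets=n_sets,
        set_size=set_size,
    )


def threshold_at_alpha(model: NullModel, direction: str) -> float:
    """The alpha-tail threshold: ``below`` -> alpha-quantile of the null means
    (their minimum at alpha=0.001 with 1000 sets), ``above`` -> (1-alpha)-quantile
    (their maximum)."""
    if direction == "below":
        return model.threshold_low
    if direction == "above":
        return model.threshold_high
    raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")


def exceedance_stats(
    track: LandscapeTrack | np.ndarray,
    model: NullModel,
    threshold: float | None = None,
    direction: str = "below",
) -> ExceedanceReport:
    """Observed threshold-crossing windows vs the null expectation.

    ``p_hat`` is the add-one-corrected null crossing rate ``(k+1)/(n_sets+1)``
    (never exactly 0: 1000 draws cannot resolve p < 1/1001); the p-value is
    the upper binomial tail of observing at least the observed count.
    """
    smoothed = track.smoothed if isinstance(track, LandscapeTrack) else np.asarray(track, float)
    if threshold is None:
        threshold = threshold_at_alpha(model, direction)
    valid = smoothed[np.isfinite(smoothed)]
    n_windows = len(valid)
    if direction == "below":
        observed = int(np.sum(valid < threshold))
        k = int(np.sum(model.null_values < threshold))
    elif direction == "above":
        observed = int(np.sum(valid > threshold))
        k = int(np.sum(model.null_values > threshold))
    else:
        raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")
    p_hat = (k + 1) / (model.n_sets + 1)
    p_value = float(stats.binom.sf(observed - 1, n_windows, p_hat))
    return ExceedanceReport(
        statistic=model.statistic,
        direction=direction,
        threshold=float(threshold),
        n_windows=n_windows,
        observed_count=observed,
        p_hat=float(p_hat),
        expected_count=float(n_windows * p_hat),
        p_value=p_value,
    )


@dataclass
class NormalityResult:
    W: float
    p_value: float
    normal: bool


def normality_check(values, reject_below: float = 0.01) -> NormalityResult:
    """Shapiro-Wilk normality test; normality retained unless p < 0.01."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise UndefinedValueError("constant sample; normality test undefined")
    res = stats.shapiro(x)
    return NormalityResult(W=float(res.statistic), p_value=float(res.pvalue),
                           normal=bool(res.pvalue >= reject_below))
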