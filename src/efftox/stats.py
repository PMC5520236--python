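"""Binomial confidence intervals used in design discussions.

After observing, say, three toxicities in three patients, the plausible
range of the true event rate is wide: the 95% Clopper-Pearson ("exact")
lower bound for 3/3 is 29.2%, and the Wilson score lower bound is
43.9%. These intervals inform how seriously to treat extreme early
outcomes when tuning admissibility certainties.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

__all__ = ["BinomialInterval", "binomial_ci"]

_METHODS = {"exact": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class BinomialInterval:
    """A two-sided confidence interval for a binomial proportion."""

    lower: float
    upper: float
    method: str
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError("interval bounds must satisfy 0 <= lower <= upper <= 1")


def binomial_ci(
    successes: int, trials: int, level: float = 0.95, method: str = "exact"
) -> BinomialInterval:
    """Two-sided binomial CI: Clopper-Pearson ("exact") or Wilson score.

    At full success the exact interval's upper bound is 1 and the lower
    bound is the alpha/2 beta quantile, i.e. (alpha/2)^(1/n) — the
    two-sided convention (a one-sided 95% bound would differ).

    Examples
    --------
    >>> round(binomial_ci(3, 3, 0.95, "exact").lower, 3)
    0.292
    >>> round(binomial_ci(3, 3, 0.95, "wilson").lower, 3)
    0.439
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    lower, upper = proportion_confint(successes, trials, alpha=1 - level, method=_METHODS[method])
    # statsmodels returns the degenerate bound at 0/n and n/n already
    return BinomialInterval(lower=float(lower), upper=float(upper), method=method, level=level)
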