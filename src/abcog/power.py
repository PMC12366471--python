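"""One-sample t-test power and minimal sample size.

Exact computation under the noncentral t distribution: for a true
standardized effect delta and sample size n, the test statistic follows a
noncentral t with df = n - 1 and noncentrality delta * sqrt(n).  The exact
distribution (rather than a normal approximation) is used because planning
targets are sensitive to the tail behaviour at moderate n.
"""

from __future__ import annotations

from scipy import stats

TAILS = ("one", "two")


def power_one_sample_t(n: int, effect_size: float, alpha: float = 0.05,
                       tails: str = "two") -> float:
    """Rejection probability of a one-sample t-test.

    ``tails="one"`` assumes the test is directed at the sign of
    ``effect_size``; ``tails="two"`` sums both rejection regions.
    With ``effect_size = 0`` the power equals ``alpha`` (the size of the
    test).
    """
    if n < 2:
        raise ValueError("n must be >= 2 for a one-sample t-test")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if tails not in TAILS:
        raise ValueError(f"tails must be one of {TAILS}, got {tails!r}")
    df = n - 1
    nc = abs(effect_size) * n ** 0.5
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
    return float(power)


def sample_size_for_power(effect_size: float, alpha: float = 0.05,
                          tails: str = "two", target_power: float = 0.9,
                          max_n: int = 1_000_000) -> int:
    """Smallest n whose one-sample t-test power reaches ``target_power``.

    Raises when the target is unreachable (``effect_size = 0`` or target
    not attained by ``max_n``).
    """
    if effect_size == 0:
        raise ValueError("power cannot exceed alpha at effect size 0")
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must lie in (0, 1), got {target_power}")
    # bracket by doubling, then binary search on the monotone power curve
    lo, hi = 2, 2
    while power_one_sample_t(hi, effect_size, alpha, tails) < target_power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise ValueError(f"target power {target_power} not reachable by n={max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_one_sample_t(mid, effect_size, alpha, tails) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
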