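"""Estimation statistics: mean differences with BCa bootstrap CIs and
permutation t-tests.

The quantities reported here follow the estimation-statistics school:
instead of a bare p-value, each comparison is summarized by its effect size
(the mean difference), a nonparametric bias-corrected and accelerated (BCa)
bootstrap confidence interval, and a two-sided permutation test of the mean
difference.  Paired designs resample pairs and build the permutation null by
random sign flips of within-pair differences; unpaired designs resample
within groups and permute group labels.

p-values are the raw proportion of resampled statistics at least as extreme
as the observed one (no add-one correction), so extreme results format as
``0.000``; the add-one variant is available via ``add_one=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "EstimationResult",
    "mean_difference",
    "bca_ci",
    "permutation_test",
    "estimate",
]


@dataclass
class EstimationResult:
    """A two-group comparison: effect size, BCa CI and permutation p."""

    design: str
    delta: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_boot: int = 5000
    p_value: float = float("nan")
    n_perm: int = 5000
    seed: int | None = None
    n_test: int = 0
    n_control: int = 0

    @property
    def p_formatted(self) -> str:
        """p to three decimals; extreme results print as '0.000'."""
        return f"{self.p_value:.3f}"

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "mean_difference": self.delta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n_boot": self.n_boot,
            "p_value": round(self.p_value, 3),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_test": self.n_test,
            "n_control": self.n_control,
        }


def _check_design(design: str) -> str:
    if design not in ("paired", "unpaired"):
        raise ValueError(f"design must be 'paired' or 'unpaired', got {design!r}")
    return design


def _as_groups(test, control, design):
    t = np.asarray(test, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if t.size == 0 or c.size == 0:
        raise ValueError("empty group")
    if design == "paired" and t.size != c.size:
        raise ValueError(
            f"paired design requires equal lengths (got {t.size} and {c.size})"
        )
    return t, c


def mean_difference(test, control, design: str = "unpaired") -> float:
    """Mean difference test - control.

    Unpaired: mean(test) - mean(control).  Paired: mean of within-pair
    differences (algebraically equal, but the paired form requires aligned,
    equal-length inputs).
    """
    _check_design(design)
    t, c = _as_groups(test, control, design)
    if design == "paired":
        return float(np.mean(t - c))
    return float(np.mean(t) - np.mean(c))


def _jackknife_deltas(t: np.ndarray, c: np.ndarray, design: str) -> np.ndarray:
    """Leave-one-out mean differences (over pairs for paired designs)."""
    if design == "paired":
        d = t - c
        n = d.size
        s = d.sum()
        return (s - d) / (n - 1)
    nt, nc = t.size, c.size
    st, sc = t.sum(), c.sum()
    # leave one out of test, control fixed; then the converse
    loo_t = (st - t) / (nt - 1) - sc / nc
    loo_c = st / nt - (sc - c) / (nc - 1)
    return np.concatenate([loo_t, loo_c])


def bca_ci(
    test,
    control,
    design: str = "unpaired",
    n_boot: int = 5000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean difference.

    Bootstrap resamples within groups (unpaired) or over pairs (paired).
    The bias correction z0 comes from the fraction of bootstrap replicates
    below the observed difference; the acceleration a from the skewness of
    leave-one-out jackknife values.  A degenerate bootstrap distribution
    (all replicates equal) collapses the CI to a point with a warning.
    """
    _check_design(design)
    t, c = _as_groups(test, control, design)
    if min(t.size, c.size) < 3:
        raise ValueError("group sizes must be >= 3 for a bootstrap CI")
    rng = np.random.default_rng(seed)
    theta = mean_difference(t, c, design)

    if design == "paired":
        d = t - c
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        boot = d[idx].mean(axis=1)
    else:
        it = rng.integers(0, t.size, size=(n_boot, t.size))
        ic = rng.integers(0, c.size, size=(n_boot, c.size))
        boot = t[it].mean(axis=1) - c[ic].mean(axis=1)

    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; CI collapsed to a point")
        return theta, theta

    alpha = 1.0 - level
    prop = np.mean(boot < theta)
    # guard against z0 = +/- inf when theta falls outside the bootstrap range
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1.0 - 1.0 / (2 * n_boot))
    z0 = _sps.norm.ppf(prop)

    jack = _jackknife_deltas(t, c, design)
    resid = jack.mean() - jack
    denom = np.sum(resid**2) ** 1.5
    a = 0.0 if denom == 0 else float(np.sum(resid**3) / (6.0 * denom))

    z_lo = _sps.norm.ppf(alpha / 2)
    z_hi = _sps.norm.ppf(1 - alpha / 2)
    p_lo = _sps.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    p_hi = _sps.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [p_lo, p_hi])
    return float(lo), float(hi)


def permutation_test(
    test,
    control,
    design: str = "unpaired",
    n_perm: int = 5000,
    seed=None,
    add_one: bool = False,
) -> float:
    """Two-sided permutation test of the mean difference.

    The statistic is |mean difference|.  Unpaired nulls permute the group
    labels of the pooled sample; paired nulls flip the signs of within-pair
    differences.  Returns the raw proportion of resampled |statistics| that
    reach the observed one (``add_one`` applies the (b+1)/(R+1) correction).
    """
    _check_design(design)
    t, c = _as_groups(test, control, design)
    if min(t.size, c.size) < 2:
        raise ValueError("group sizes must be >= 2 for a permutation test")
    rng = np.random.default_rng(seed)
    obs = abs(mean_difference(t, c, design))
    tol = 1e-12 * max(1.0, obs)

    if design == "paired":
        d = t - c
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = np.abs((signs * d).mean(axis=1))
    else:
        # canonical form (sorted pool, smaller group first) so that swapping
        # the test/control labels reproduces the identical null stream
        pooled = np.sort(np.concatenate([t, c]))
        n, m = pooled.size, min(t.size, c.size)
        # vectorized label permutations: argsort of uniforms
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm = pooled[order]
        null = np.abs(perm[:, :m].mean(axis=1) - perm[:, m:].mean(axis=1))

    hits = int(np.sum(null >= obs - tol))
    if add_one:
        return float((hits + 1) / (n_perm + 1))
    return float(hits / n_perm)


def estimate(
    test,
    control,
    design: str = "unpaired",
    n_boot: int = 5000,
    n_perm: int = 5000,
    level: float = 0.95,
    seed=None,
    add_one: bool = False,
) -> EstimationResult:
    """Full comparison: mean difference, BCa CI and permutation p."""
    t, c = _as_groups(test, control, _check_design(design))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    s_boot, s_perm = ss.spawn(2)
    delta = mean_difference(t, c, design)
    lo, hi = bca_ci(t, c, design, n_boot=n_boot, level=level, seed=s_boot)
    p = permutation_test(t, c, design, n_perm=n_perm, seed=s_perm, add_one=add_one)
    return EstimationResult(
        design=design,
        delta=delta,
        ci_low=lo,
        ci_high=hi,
        level=level,
        n_boot=n_boot,
        p_value=p,
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        n_test=t.size,
        n_control=c.size,
    )
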