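"""Catch-curve construction and total-mortality estimation.

The catch curve is the plot of ln(frequency) against age for a catch sample.
Under constant recruitment and constant mortality, abundance decays as
exp(-Z * a) above the age of full recruitment, so the slope of the descending
limb of the log age-frequency distribution estimates -Z, the total
instantaneous mortality (Z = M + F, natural plus fishing mortality).

Workflow: :func:`build_age_frequency` bins aged lengths into 0.2-yr classes,
:func:`truncate_right_tail` discards observations beyond a long zero-catch
gap, :func:`full_recruitment_age` locates the onset of the descending limb as
the maximum of a smoothing spline through the class frequencies, and
:func:`estimate_z` regresses ln(count) on age over the limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .growth import GrowthParams, ages_from_lengths

logger = logging.getLogger(__name__)

__all__ = [
    "AgeFrequency",
    "CatchCurveFit",
    "MinimumSampleSize",
    "age_class_index",
    "bin_lengths",
    "build_age_frequency",
    "truncate_right_tail",
    "full_recruitment_age",
    "descending_limb",
    "estimate_z",
    "fit_catch_curve",
    "minimum_sample_size",
]

DEFAULT_CLASS_WIDTH = 0.2
DEFAULT_GAP = 4


@dataclass
class AgeFrequency:
    """Binned age-frequency distribution on a regular grid of age classes.

    Classes are half-open on the right: an age on a class boundary belongs to
    the upper class.  ``midpoints`` are strictly increasing with constant
    spacing ``class_width``; ``counts`` align with them.  The number of
    records whose length exceeded the growth asymptote (and were dropped
    during ageing) is carried along so that the record count is conserved:
    ``counts.sum() + n_dropped_over_linf == n input records``.
    """

    class_width: float
    midpoints: np.ndarray
    counts: np.ndarray
    n_dropped_over_linf: int = 0

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.midpoints.shape != self.counts.shape:
            raise ValueError("midpoints and counts must have equal length")
        if self.midpoints.size:
            d = np.diff(self.midpoints)
            if np.any(d <= 0):
                raise ValueError("midpoints must be strictly increasing")
            if d.size and not np.allclose(d, self.class_width, rtol=1e-6, atol=1e-9):
                raise ValueError("midpoint spacing must equal class_width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return int(self.midpoints.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """(midpoints, counts) of the classes with positive count."""
        m = self.counts > 0
        return self.midpoints[m], self.counts[m]


@dataclass
class CatchCurveFit:
    """OLS fit of ln(count) on age over the descending limb.

    ``z`` is the total instantaneous mortality reported as a positive
    magnitude (the negated regression slope); ``ci95`` is the 95% confidence
    interval on that magnitude, from the t distribution with n-2 df.
    """

    z: float
    intercept_b: float
    se_z: float
    ci95: tuple[float, float]
    r2: float
    recruit_age: float
    ages_used: np.ndarray
    n_classes: int
    n_records: int | None = None
    n_dropped: int | None = None

    def as_dict(self) -> dict:
        d = {
            "z": self.z, "se_z": self.se_z,
            "ci_lo": self.ci95[0], "ci_hi": self.ci95[1],
            "intercept_b": self.intercept_b, "r2": self.r2,
            "recruit_age": self.recruit_age, "n_classes": self.n_classes,
        }
        if self.n_records is not None:
            d["n_records"] = self.n_records
        if self.n_dropped is not None:
            d["n_dropped"] = self.n_dropped
        return d


def age_class_index(ages, class_width: float) -> np.ndarray:
    """Index of the half-open age class [i*w, (i+1)*w) containing each age.

    The grid is anchored at age zero, so the same age always falls in the
    same class; an age exactly on a boundary belongs to the upper class.
    """
    return np.floor(np.asarray(ages, dtype=float) / class_width).astype(int)


def bin_lengths(lengths) -> pd.Series:
    """Length-frequency table on 1-mm half-open intervals [i, i+1).

    Returns a Series indexed by the integer lower bound of each occupied
    interval (intermediate empty intervals included), values are counts.
    Empty input yields an empty table.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return pd.Series(dtype=int, name="count")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    bins = np.floor(lengths).astype(int)
    lo, hi = bins.min(), bins.max()
    idx = np.arange(lo, hi + 1)
    counts = np.bincount(bins - lo, minlength=idx.size)
    return pd.Series(counts, index=idx, name="count")


def build_age_frequency(
    lengths,
    p: GrowthParams,
    class_width: float = DEFAULT_CLASS_WIDTH,
    over_linf: str = "drop",
) -> AgeFrequency:
    """Age a set of measured lengths and bin the ages into regular classes.

    Ages are assigned to half-open classes [m - w/2, m + w/2) where the
    midpoints are m = (i + 1/2) * w on an absolute grid anchored at age zero,
    so the same age always falls in the same class regardless of the sample.
    """
    if class_width <= 0:
        raise ValueError("class_width must be positive")
    lengths = np.asarray(lengths, dtype=float)
    ages, n_dropped = ages_from_lengths(lengths, p, over_linf=over_linf)
    if ages.size == 0:
        raise ValueError("no ageable records (all lengths at or above linf)")
    idx = age_class_index(ages, class_width)
    lo, hi = idx.min(), idx.max()
    grid = np.arange(lo, hi + 1)
    counts = np.bincount(idx - lo, minlength=grid.size)
    midpoints = (grid + 0.5) * class_width
    return AgeFrequency(class_width, midpoints, counts, n_dropped)


def truncate_right_tail(af: AgeFrequency, gap: int = DEFAULT_GAP) -> AgeFrequency:
    """Drop everything from the first run of >= ``gap`` zero-count classes on.

    Observations at the right end of the age-frequency distribution that
    follow a long zero-catch gap are scattered strays that would otherwise
    lever the regression; the cut happens at the first (leftmost) qualifying
    gap to the right of the modal class, and classes before it are left
    untouched.  Gaps left of the mode (e.g. below a sparse ascending limb)
    are not right-end gaps and never trigger truncation.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    counts = af.counts
    start = int(np.argmax(counts)) if counts.size else 0
    run = 0
    cut = None
    for i, c in enumerate(counts[start:], start=start):
        if c == 0:
            run += 1
            if run == gap:
                cut = i - gap + 1
                break
        else:
            run = 0
    if cut is None:
        return af
    return AgeFrequency(
        af.class_width, af.midpoints[:cut], counts[:cut], af.n_dropped_over_linf
    )


def full_recruitment_age(
    af: AgeFrequency,
    lam: float | None = None,
    on_log: bool = False,
) -> float:
    """Age of full recruitment: the maximizer of a spline through the curve.

    A cubic smoothing spline is fitted to the class frequencies against the
    class midpoints (smoothing parameter ``lam``; ``None`` selects it by
    generalized cross-validation) and evaluated on a dense grid (step
    class_width/20) over the observed age range; the abscissa of its maximum
    is returned.  With fewer than 5 classes an interpolating cubic spline is
    used instead, since the GCV criterion needs at least 5 points.

    Set ``on_log=True`` to fit the spline to ln(count + 1) instead of the raw
    counts (the maximizer of a monotone transform differs only through the
    smoothing step).

    Requires at least 4 classes with nonzero counts.
    """
    x, c = af.midpoints, af.counts
    if int((c > 0).sum()) < 4:
        raise ValueError("too few classes for spline (need >= 4 nonzero)")
    y = np.log1p(c) if on_log else c.astype(float)
    if x.size >= 5:
        spline = make_smoothing_spline(x, y, lam=lam)
    else:
        spline = CubicSpline(x, y)
    step = af.class_width / 20.0
    grid = np.arange(x[0], x[-1] + step / 2, step)
    grid = np.clip(grid, x[0], x[-1])
    return float(grid[np.argmax(spline(grid))])


def descending_limb(af: AgeFrequency, recruit_age: float) -> AgeFrequency:
    """Classes from the one containing ``recruit_age`` rightward.

    The peak class itself is included: the limb starts at the class whose
    half-open interval contains the recruitment age.  Zero-count classes are
    retained here (they matter for truncation bookkeeping) and skipped later
    by the regression, where ln is undefined.
    """
    start = af.midpoints > recruit_age - af.class_width / 2
    return AgeFrequency(
        af.class_width, af.midpoints[start], af.counts[start], af.n_dropped_over_linf
    )


def estimate_z(af: AgeFrequency, recruit_age: float) -> CatchCurveFit:
    """Catch-curve regression: OLS of ln(count) on age over the limb.

    Z is the negated slope, reported as a positive magnitude, with its
    standard error, t-based 95% CI, and R^2.  Zero-count classes inside the
    limb are skipped (their logarithm is undefined).  Requires at least 3
    usable classes.
    """
    limb = descending_limb(af, recruit_age)
    ages, counts = limb.nonzero()
    n = ages.size
    if n < 3:
        raise ValueError(
            f"insufficient descending limb: {n} usable classes (need >= 3)"
        )
    y = np.log(counts)
    res = stats.linregress(ages, y)
    slope, intercept = res.slope, res.intercept
    se = res.stderr
    tcrit = stats.t.ppf(0.975, n - 2)
    z = -slope
    lo, hi = z - tcrit * se, z + tcrit * se
    return CatchCurveFit(
        z=float(z),
        intercept_b=float(intercept),
        se_z=float(se),
        ci95=(float(lo), float(hi)),
        r2=float(res.rvalue ** 2),
        recruit_age=float(recruit_age),
        ages_used=ages,
        n_classes=n,
        n_dropped=limb.n_dropped_over_linf,
    )


def fit_catch_curve(
    lengths,
    p: GrowthParams,
    class_width: float = DEFAULT_CLASS_WIDTH,
    gap: int = DEFAULT_GAP,
    over_linf: str = "drop",
    spline_lam: float | None = None,
    spline_on_log: bool = False,
) -> CatchCurveFit:
    """Full single-group pipeline: bin, truncate, locate the limb, regress."""
    lengths = np.asarray(lengths, dtype=float)
    af = build_age_frequency(lengths, p, class_width=class_width, over_linf=over_linf)
    af = truncate_right_tail(af, gap=gap)
    recruit = full_recruitment_age(af, lam=spline_lam, on_log=spline_on_log)
    fit = estimate_z(af, recruit)
    fit.n_records = int(lengths.size)
    return fit


@dataclass
class MinimumSampleSize:
    """Result of the bootstrap minimum-sample-size search.

    ``n_min`` is the smallest candidate subsample size whose mean
    Kolmogorov-Smirnov distance to the full empirical length distribution
    is at or below the criterion, or ``None`` when no candidate attains it
    (``attained`` False); ``profile`` maps each candidate n to its mean
    distance.
    """

    n_min: int | None
    attained: bool
    criterion_eps: float
    profile: dict[int, float] = field(default_factory=dict)


def _ks_to_full(sub: np.ndarray, full_sorted: np.ndarray) -> float:
    # sup_x |ECDF_sub(x) - ECDF_full(x)|; both ECDFs are right-continuous step
    # functions, so the supremum is attained at one of the pooled jump points
    sub = np.sort(sub)
    pts = np.concatenate([sub, full_sorted])
    f_sub = np.searchsorted(sub, pts, side="right") / sub.size
    f_full = np.searchsorted(full_sorted, pts, side="right") / full_sorted.size
    return float(np.max(np.abs(f_sub - f_full)))


def minimum_sample_size(
    lengths,
    criterion_eps: float = 0.05,
    n_grid=None,
    reps: int = 500,
    seed: int | None = None,
) -> MinimumSampleSize:
    """Bootstrap search for the smallest reliable sample size.

    For each candidate n, ``reps`` subsamples are drawn without replacement
    and the mean KS distance between subsample and full empirical length
    distributions is computed; the smallest n with mean distance <=
    ``criterion_eps`` is returned.  Deterministic given ``seed``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_grid is None:
        n_grid = list(range(25, lengths.size + 1, 25))
    n_grid = sorted(int(n) for n in n_grid)
    if not n_grid or n_grid[-1] > lengths.size:
        raise ValueError("n_grid must be non-empty with max <= len(lengths)")
    rng = np.random.default_rng(seed)
    full_sorted = np.sort(lengths)
    profile: dict[int, float] = {}
    n_min = None
    for n in n_grid:
        dists = np.empty(reps)
        for r in range(reps):
            sub = rng.choice(lengths, size=n, replace=False)
            dists[r] = _ks_to_full(sub, full_sorted)
        profile[n] = float(dists.mean())
        if n_min is None and profile[n] <= criterion_eps:
            n_min = n
            break
    return MinimumSampleSize(
        n_min=n_min,
        attained=n_min is not None,
        criterion_eps=criterion_eps,
        profile=profile,
    )
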