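"""ANCOVA comparison of catch-curve slopes across factors.

Each comparison stacks the descending-limb observations (age class midpoint,
ln count) of several groups and fits the full-interaction linear model

    ln C ~ group + age + group:age

The F statistic of the group:age interaction (Type II sums of squares, so
unbalanced group sizes are handled symmetrically) tests equality of the age
slopes — i.e. of total instantaneous mortality Z — across groups.  Because
the model is saturated in the group x age cell means, the per-group slopes it
implies coincide exactly with separate per-group OLS fits, which are reported
alongside.

Also here: single-df interaction contrasts for post-hoc pairwise slope
tests, the year-trend regression for MA-level mortality series, the pooled
Student t comparison of species mean mortality, and frequency-matched
subsampling used to balance open-access strata before a regional comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .curves import AgeFrequency, CatchCurveFit, estimate_z

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeComparison",
    "SubsampleSpec",
    "ancova_slopes",
    "nested_ancova",
    "posthoc_pairs",
    "temporal_trend",
    "species_ttest",
    "frequency_matched_subsample",
]


@dataclass
class SlopeComparison:
    """Result of an ANCOVA slope-equality test across factor levels."""

    design: str
    f_stat: float
    df_num: int
    df_den: int
    p: float
    group_fits: dict[str, CatchCurveFit] = field(default_factory=dict)
    _model: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")

    @property
    def levels(self) -> list[str]:
        return list(self.group_fits)


@dataclass(frozen=True)
class SubsampleSpec:
    """Target size and seed for a frequency-matched subsample."""

    n_target: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")


def _limb_frame(level: str, af: AgeFrequency) -> pd.DataFrame:
    ages, counts = af.nonzero()
    if ages.size < 3:
        raise ValueError(
            f"level {level!r} has {ages.size} usable classes (need >= 3)"
        )
    return pd.DataFrame({"level": level, "age": ages, "ln_c": np.log(counts)})


def _interaction_anova(data: pd.DataFrame, design: str,
                       groups: Mapping[str, AgeFrequency]) -> SlopeComparison:
    model = smf.ols("ln_c ~ C(level) * age", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(level):age"]
    f_stat, p = float(row["F"]), float(row["PR(>F)"])
    # perfect-fit degeneracy: noiseless groups drive both the interaction and
    # the residual sums of squares to machine zero, and their ratio is junk
    ss_total = float(np.sum((data["ln_c"] - data["ln_c"].mean()) ** 2))
    tol = 1e-12 * max(ss_total, 1.0)
    if float(table.loc["Residual", "sum_sq"]) <= tol:
        if float(row["sum_sq"]) <= tol:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    fits = {
        lvl: estimate_z(af, recruit_age=float(af.midpoints[af.counts > 0][0]))
        for lvl, af in groups.items()
    }
    return SlopeComparison(
        design=design,
        f_stat=f_stat,
        df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]),
        p=p,
        group_fits=fits,
        _model=model,
    )


def ancova_slopes(groups: Mapping[str, AgeFrequency], design: str = "MR") -> SlopeComparison:
    """Test equality of catch-curve slopes across the levels of one factor.

    ``groups`` maps each factor level to the descending limb of its age
    frequency (already truncated and restricted to ages at or above full
    recruitment).  At least 2 levels, each with at least 3 positive-count
    classes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 levels")
    data = pd.concat(
        [_limb_frame(str(lvl), af) for lvl, af in groups.items()],
        ignore_index=True,
    )
    return _interaction_anova(data, design, {str(k): v for k, v in groups.items()})


NESTED_SEP = "|"


def nested_ancova(groups: Mapping[tuple, AgeFrequency],
                  design: str = "S(MR)") -> SlopeComparison:
    """Slope ANCOVA for management regime nested within site.

    ``groups`` is keyed by (site, regime) cells, each holding the limb of the
    length data pooled over that site's fishing grounds.  With the nested
    coding every (site, regime) cell carries its own slope, so the interaction
    F tests homogeneity of Z across the cells (numerator df = cells - 1).
    """
    flat = {NESTED_SEP.join(map(str, key)): af for key, af in groups.items()}
    if len(flat) != len(groups):
        raise ValueError("duplicate (site, regime) cells after labeling")
    return ancova_slopes(flat, design=design)


def _slope_contrast(model, levels: Sequence[str], a: str, b: str) -> np.ndarray:
    """Row vector picking slope(a) - slope(b) out of the interaction model."""
    names = model.model.exog_names
    vec = np.zeros(len(names))

    def add(level: str, sign: float) -> None:
        name = f"C(level)[T.{level}]:age"
        if name in names:
            vec[names.index(name)] += sign
        # reference level: its slope is the bare `age` coefficient, which
        # cancels from any pairwise difference, so nothing to add.

    add(a, +1.0)
    add(b, -1.0)
    return vec


def posthoc_pairs(
    comparison: SlopeComparison,
    pairs: Sequence[tuple[str, str]],
    adjust: str | None = None,
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise slope-difference tests within a fitted ANCOVA.

    Each pair is tested by the single-df contrast on the difference of age
    slopes inside the full interaction model (F = t^2 on the residual df).
    ``adjust="holm"`` applies Holm's step-down correction across the pairs;
    the default reports unadjusted p-values.
    """
    model = comparison._model
    if model is None:
        raise ValueError("comparison carries no fitted model")
    levels = comparison.levels
    out: dict[tuple[str, str], dict[str, float]] = {}
    ss_total = float(model.centered_tss)
    degenerate = model.ssr <= 1e-12 * max(ss_total, 1.0)
    for a, b in pairs:
        for lvl in (a, b):
            if lvl not in levels:
                raise ValueError(f"unknown level {lvl!r}; have {levels}")
        vec = _slope_contrast(model, levels, a, b)
        if degenerate:
            # perfect fit: residual variance is machine zero and the t ratio
            # is undefined; decide on the exact slope difference instead
            diff = float(vec @ model.params)
            f, p = (0.0, 1.0) if abs(diff) <= 1e-9 else (np.inf, 0.0)
        else:
            tt = model.t_test(vec)
            t = float(np.squeeze(tt.tvalue))
            f, p = t * t, float(np.squeeze(tt.pvalue))
        out[(a, b)] = {"f": f, "p": p, "df_num": 1, "df_den": int(model.df_resid)}
    if adjust == "holm":
        keys = list(out)
        adj = multipletests([out[k]["p"] for k in keys], method="holm")[1]
        for k, p in zip(keys, adj):
            out[k]["p"] = float(p)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def temporal_trend(z_by_ma_year: Sequence[tuple]) -> dict:
    """Linear trend of annual MA-level mortality on year.

    ``z_by_ma_year`` holds (ma, year, z) triples, one per management area and
    year.  Year enters as a continuous single-df predictor, so the F test has
    (1, n - 2) degrees of freedom.
    """
    rows = list(z_by_ma_year)
    if len(rows) < 3:
        raise ValueError("need at least 3 (ma, year, z) points")
    years = np.array([r[1] for r in rows], dtype=float)
    z = np.array([r[2] for r in rows], dtype=float)
    n = len(rows)
    res = stats.linregress(years, z)
    if np.isnan(res.stderr) or res.stderr == 0:
        f = 0.0 if res.slope == 0 else np.inf
        p = 1.0 if res.slope == 0 else 0.0
    else:
        t = res.slope / res.stderr
        f = t * t
        p = float(stats.f.sf(f, 1, n - 2))
    return {
        "f": float(f), "df_num": 1, "df_den": n - 2, "p": float(p),
        "slope": float(res.slope), "intercept": float(res.intercept),
        "r2": float(res.rvalue ** 2), "n": n,
    }


def species_ttest(z_species1: Sequence[float], z_species2: Sequence[float]) -> dict:
    """Pooled-variance Student t-test between two sets of Z estimates.

    df = n1 + n2 - 2.  Degenerate input with zero variance in both samples
    (t undefined unless the means differ infinitely) raises.
    """
    a = np.asarray(z_species1, dtype=float)
    b = np.asarray(z_species2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per species")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": int(a.size + b.size - 2), "p": float(p),
            "mean1": float(a.mean()), "mean2": float(b.mean())}


def _largest_remainder(counts: np.ndarray, n_target: int) -> np.ndarray:
    """Integer quotas proportional to ``counts`` summing exactly to n_target."""
    total = counts.sum()
    exact = n_target * counts / total
    base = np.floor(exact).astype(int)
    short = n_target - int(base.sum())
    if short:
        remainder = exact - base
        # ties broken toward larger classes, then lower bin index: stable,
        # deterministic allocation
        order = np.lexsort((np.arange(counts.size), -counts, -remainder))
        base[order[:short]] += 1
    return base


def frequency_matched_subsample(
    records: pd.DataFrame,
    spec: SubsampleSpec,
    class_of=None,
) -> pd.DataFrame:
    """Downsample records to ``n_target`` while preserving class proportions.

    Per-class quotas are the source's class proportions times ``n_target``,
    rounded by the largest-remainder rule so they sum exactly to the target;
    individuals are then drawn without replacement within each class, seeded.
    ``class_of`` maps the records to class labels (default: 1-mm length bin;
    pass e.g. an age-class labeller to match on age structure — both induce
    the same ordering since age is monotone in length).
    """
    n = len(records)
    if spec.n_target > n:
        raise ValueError(f"n_target={spec.n_target} exceeds source size {n}")
    if class_of is None:
        labels = np.floor(records["length_mm"].to_numpy(dtype=float)).astype(int)
    else:
        labels = np.asarray(class_of(records))
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    quotas = _largest_remainder(counts, spec.n_target)
    if np.any(quotas > counts):  # cannot happen when matching a sample to itself
        raise ValueError("class quota exceeds class count")
    rng = np.random.default_rng(spec.seed)
    take: list[np.ndarray] = []
    for ci, q in enumerate(quotas):
        if q == 0:
            continue
        members = np.flatnonzero(inverse == ci)
        take.append(rng.choice(members, size=q, replace=False))
    idx = np.concatenate(take) if take else np.array([], dtype=int)
    return records.iloc[np.sort(idx)]
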