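"""Study orchestration: regional, local and temporal mortality analyses.

Ties the pieces together the way the study design demands:

* **regional** — one-way ANCOVA of catch-curve slopes across the three
  management regimes (no-take / managed / open access) on the comparative
  snapshot, with frequency-matched downsampling to stop one open-access site
  from dominating the pooled curve, pairwise post-hoc slope contrasts,
  percent mortality differences against the no-take reference, and a
  fishing-mortality decomposition Z = M + F with M taken from the no-take
  area.  For a species whose extraction is banned in open access areas,
  positive estimated F there is reported as inferred illegal fishing.
* **local** — management regime nested within site, plus per-site ANCOVAs of
  the individual management areas against the pooled open-access grounds.
* **temporal** — per-(management area, year) fits, a single-df year-trend
  test on the annual Z series, per-area across-year ANCOVAs, and the pooled
  Student t comparison of the two resources' mean mortality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design
from .compare import (
    SubsampleSpec,
    ancova_slopes,
    frequency_matched_subsample,
    nested_ancova,
    posthoc_pairs,
    species_ttest,
    temporal_trend,
)
from .config import AnalysisConfig, PipelineConfig, default_config
from .curves import (
    CatchCurveFit,
    build_age_frequency,
    descending_limb,
    estimate_z,
    full_recruitment_age,
    truncate_right_tail,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MortalityDecomposition",
    "percent_difference",
    "decompose_mortality",
    "prepare_limb",
    "run_regional",
    "run_local",
    "run_temporal",
]


@dataclass(frozen=True)
class MortalityDecomposition:
    """Z split against the no-take natural-mortality reference.

    ``f_est = z - m_ref`` exactly; a negative value is diagnostic of
    reference error (or sampling noise) and is flagged, never clamped.
    ``pct_vs_ref`` is the percent excess over the reference, rounded
    half-away-from-zero to an integer.
    """

    z: float
    m_ref: float
    f_est: float
    pct_vs_ref: int
    below_reference: bool


def percent_difference(z_a: float, z_ref: float) -> int:
    """100 * (z_a - z_ref) / z_ref, rounded half-away-from-zero to integer."""
    if z_ref <= 0:
        raise ValueError("reference mortality must be positive")
    x = 100.0 * (z_a - z_ref) / z_ref
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def decompose_mortality(fit: CatchCurveFit, nt_fit: CatchCurveFit) -> MortalityDecomposition:
    z, m_ref = fit.z, nt_fit.z
    f_est = z - m_ref
    return MortalityDecomposition(
        z=z, m_ref=m_ref, f_est=f_est,
        pct_vs_ref=percent_difference(z, m_ref),
        below_reference=f_est < 0,
    )


def prepare_limb(lengths, growth, analysis: AnalysisConfig):
    """Build, truncate and locate the descending limb of one group.

    Returns (limb AgeFrequency, truncated AgeFrequency, recruit age).
    """
    af = build_age_frequency(
        lengths, growth,
        class_width=analysis.class_width, over_linf=analysis.over_linf,
    )
    af = truncate_right_tail(af, gap=analysis.gap)
    recruit = full_recruitment_age(
        af, lam=analysis.spline_lam, on_log=analysis.spline_on_log
    )
    return descending_limb(af, recruit), af, recruit


def _group_fit(lengths, growth, analysis: AnalysisConfig):
    limb, af, recruit = prepare_limb(lengths, growth, analysis)
    fit = estimate_z(af, recruit)
    fit.n_records = int(np.asarray(lengths).size)
    return limb, fit


def _admissible_strata(df: pd.DataFrame, by: list[str], min_n: int):
    """Split strata into kept/excluded by minimum sample size."""
    sizes = df.groupby(by, dropna=False).size()
    kept = sizes[sizes >= min_n]
    excluded = [
        {"stratum": key if isinstance(key, tuple) else (key,), "n": int(n),
         "reason": f"n < {min_n}"}
        for key, n in sizes[sizes < min_n].items()
    ]
    mask = df.set_index(by).index.isin(kept.index)
    return df[mask], excluded


def _equalize_oaa(oaa: pd.DataFrame, seed) -> pd.DataFrame:
    """Frequency-match larger open-access sites down to the smallest one.

    Each oversized site is downsampled to the smallest site's n while
    matching its own length-frequency distribution, so no single site
    dominates the pooled regional curve.
    """
    sizes = oaa.groupby("site").size()
    target = int(sizes.min())
    if (sizes == target).all():
        return oaa
    ss = np.random.SeedSequence(seed)
    parts = []
    for (site, chunk), child in zip(oaa.groupby("site"), ss.spawn(len(sizes))):
        if len(chunk) > target:
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            chunk = frequency_matched_subsample(
                chunk, SubsampleSpec(n_target=target, seed=sub_seed)
            )
            logger.info("equalized OAA site %s to n=%d", site, target)
        parts.append(chunk)
    return pd.concat(parts, ignore_index=True)


def _snapshot(df: pd.DataFrame) -> pd.DataFrame:
    if "year" in df.columns and df["year"].notna().any():
        latest = df["year"].max()
        multi = df["year"].nunique() > 1
        if multi:
            logger.info("regional analysis restricted to snapshot year %s", latest)
            return df[df["year"] == latest]
    return df


def run_regional(records: pd.DataFrame, config: PipelineConfig | None = None,
                 seed: int | None = None) -> dict:
    """Regime-level comparison of total mortality, one report per species."""
    config = config or default_config()
    report: dict = {"analysis": "regional", "species": {}}
    for sp, sdf in records.groupby("species"):
        scfg = config.species[sp]
        ana = config.analysis
        sdf = _snapshot(sdf)
        missing = [r for r in design.REGIMES if r not in set(sdf["regime"])]
        if missing:
            raise ValueError(f"species {sp!r}: missing regimes {missing}")
        sdf, excluded = _admissible_strata(sdf, ["regime", "site"], ana.min_n)
        oaa = sdf[sdf["regime"] == design.OAA]
        if ana.oaa_equalize and len(oaa):
            oaa = _equalize_oaa(oaa, seed)
            sdf = pd.concat([sdf[sdf["regime"] != design.OAA], oaa],
                            ignore_index=True)
        limbs, fits = {}, {}
        for regime, chunk in sdf.groupby("regime"):
            limbs[regime], fits[regime] = _group_fit(
                chunk["length_mm"].to_numpy(), scfg.growth, ana
            )
        comp = ancova_slopes(limbs, design="MR")
        pairs = [(design.OAA, design.NT), (design.OAA, design.MA),
                 (design.MA, design.NT)]
        post = posthoc_pairs(comp, pairs, adjust=ana.posthoc_adjust)
        nt_fit = fits[design.NT]
        decomp = {r: decompose_mortality(fits[r], nt_fit)
                  for r in (design.MA, design.OAA)}
        pct = {r: d.pct_vs_ref for r, d in decomp.items()}
        illegal = None
        if scfg.banned_in_oaa:
            illegal = decomp[design.OAA].f_est > 0
        report["species"][sp] = {
            "fits": fits,
            "ancova": comp,
            "posthoc": post,
            "decomposition": decomp,
            "percent_vs_nt": pct,
            "excluded_strata": excluded,
            "inferred_illegal_fishing": illegal,
        }
    return report


def run_local(records: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Site-nested regime comparison plus per-site MA-vs-OAA ANCOVAs."""
    config = config or default_config()
    report: dict = {"analysis": "local", "species": {}}
    for sp, sdf in records.groupby("species"):
        scfg = config.species[sp]
        ana = config.analysis
        sdf = _snapshot(sdf)
        sdf = sdf[sdf["regime"].isin([design.MA, design.OAA])]
        sdf, excluded = _admissible_strata(sdf, ["site", "regime"], ana.min_n)
        sites = [
            s for s, chunk in sdf.groupby("site")
            if {design.MA, design.OAA} <= set(chunk["regime"])
        ]
        if not sites:
            raise ValueError(f"species {sp!r}: no site has both MA and OAA data")
        sdf = sdf[sdf["site"].isin(sites)]
        nested = None
        note = None
        cells = {
            (site, regime): _group_fit(
                chunk["length_mm"].to_numpy(), scfg.growth, ana
            )[0]
            for (site, regime), chunk in sdf.groupby(["site", "regime"])
        }
        if len(sites) >= 2:
            nested = nested_ancova(cells, design="S(MR)")
        else:
            note = "single site: nested regime-within-site test not estimable"
        per_site = {}
        for site in sites:
            chunk = sdf[sdf["site"] == site]
            groups = {}
            for ma, mdf in chunk[chunk["regime"] == design.MA].groupby("ma_id"):
                groups[f"MA-{ma}"], _ = _group_fit(
                    mdf["length_mm"].to_numpy(), scfg.growth, ana
                )
            groups[design.OAA], _ = _group_fit(
                chunk.loc[chunk["regime"] == design.OAA, "length_mm"].to_numpy(),
                scfg.growth, ana,
            )
            comp = ancova_slopes(groups, design="MR-within-site")
            lv = comp.levels
            pairs = [(a, b) for i, a in enumerate(lv) for b in lv[i + 1:]]
            per_site[site] = {
                "ancova": comp,
                "posthoc": posthoc_pairs(comp, pairs, adjust=ana.posthoc_adjust),
            }
        report["species"][sp] = {
            "nested": nested,
            "per_site": per_site,
            "excluded_strata": excluded,
            "note": note,
        }
    return report


def run_temporal(records: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Across-year mortality patterns inside the managed areas."""
    config = config or default_config()
    report: dict = {"analysis": "temporal", "species": {}}
    z_lists: dict[str, list[float]] = {}
    for sp, sdf in records.groupby("species"):
        scfg = config.species[sp]
        ana = config.analysis
        sdf = sdf[sdf["regime"] == design.MA]
        if sdf["year"].nunique() < 3:
            raise ValueError(f"species {sp!r}: need >= 3 years of MA data")
        cell_fits: dict[tuple, CatchCurveFit] = {}
        cell_limbs: dict[tuple, object] = {}
        skipped = []
        for (site, ma, year), chunk in sdf.groupby(["site", "ma_id", "year"]):
            try:
                limb, fit = _group_fit(
                    chunk["length_mm"].to_numpy(), scfg.growth, ana
                )
            except ValueError as err:
                skipped.append({"cell": (site, ma, int(year)), "n": len(chunk),
                                "reason": str(err)})
                continue
            cell_fits[(site, ma, int(year))] = fit
            cell_limbs[(site, ma, int(year))] = limb
        triples = [((site, ma), year, fit.z)
                   for (site, ma, year), fit in cell_fits.items()]
        trend = temporal_trend(triples)
        per_ma = {}
        for (site, ma), group in pd.DataFrame(
            [(s, m, y) for (s, m, y) in cell_fits], columns=["site", "ma", "year"]
        ).groupby(["site", "ma"]):
            years = sorted(group["year"])
            if len(years) < 2:
                continue
            limbs = {str(y): cell_limbs[(site, ma, y)] for y in years}
            comp = ancova_slopes(limbs, design="Y")
            pairs = [(str(a), str(b)) for i, a in enumerate(years)
                     for b in years[i + 1:]]
            per_ma[f"{site}-{ma}"] = {
                "ancova": comp,
                "posthoc": posthoc_pairs(comp, pairs, adjust=ana.posthoc_adjust),
            }
        z_lists[sp] = [fit.z for fit in cell_fits.values()]
        report["species"][sp] = {
            "cell_fits": cell_fits,
            "trend": trend,
            "per_ma": per_ma,
            "skipped_cells": skipped,
            "mean_z": float(np.mean(z_lists[sp])),
            "se_z": float(np.std(z_lists[sp], ddof=1) / np.sqrt(len(z_lists[sp]))),
        }
    if len(z_lists) == 2:
        (sp1, z1), (sp2, z2) = z_lists.items()
        report["species_ttest"] = {"species": (sp1, sp2), **species_ttest(z1, z2)}
    return report
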