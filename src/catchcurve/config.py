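"""Pipeline configuration.

A single YAML file drives the analyses: one section per species (growth
parameters and the open-access extraction-ban flag) plus shared analysis
options.  Growth asymptote and t0 are required per species because the
literature growth coefficient alone does not determine the length-age map;
the shipped defaults (loco 150 mm, limpets 110 mm, t0 = 0) are documented
placeholders, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from . import design
from .growth import GrowthParams

__all__ = ["SpeciesConfig", "AnalysisConfig", "PipelineConfig",
           "default_config", "load_config"]


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species settings: growth params and regulatory status."""

    name: str
    growth: GrowthParams
    banned_in_oaa: bool = False


@dataclass
class AnalysisConfig:
    """Shared analysis options.

    class_width : yr, width of the age classes (0.2 by default; wider
        classes can mask the onset of the descending limb).
    gap : number of consecutive zero-count classes after which the right
        tail is discarded.
    spline_lam : smoothing parameter of the recruitment spline
        (None = generalized cross-validation).
    spline_on_log : fit the recruitment spline to log counts instead of raw.
    over_linf : "drop" or "clamp" policy for over-asymptote lengths.
    min_n : minimum per-stratum sample size for a stratum to enter an
        analysis (strata below it are excluded and reported).
    oaa_equalize : frequency-match open-access site contributions down to
        the smallest admissible site before the regional comparison.
    posthoc_adjust : None (raw p-values) or "holm".
    """

    class_width: float = 0.2
    gap: int = 4
    spline_lam: float | None = None
    spline_on_log: bool = False
    over_linf: str = "drop"
    min_n: int = 200
    oaa_equalize: bool = True
    posthoc_adjust: str | None = None


@dataclass
class PipelineConfig:
    species: dict[str, SpeciesConfig] = field(default_factory=dict)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def default_config() -> PipelineConfig:
    """Built-in configuration for the two study resources."""
    return PipelineConfig(
        species={
            design.LOCO: SpeciesConfig(
                name=design.LOCO,
                growth=GrowthParams(linf=150.0, k=0.433, t0=0.0),
                banned_in_oaa=True,
            ),
            design.LIMPET: SpeciesConfig(
                name=design.LIMPET,
                growth=GrowthParams(linf=110.0, k=0.160, t0=0.0),
                banned_in_oaa=False,
            ),
        },
    )


def load_config(path) -> PipelineConfig:
    """Read a YAML config; missing keys fall back to the defaults.

    Layout::

        species:
          loco: {linf_mm: 150.0, k_per_yr: 0.433, t0_yr: 0.0, banned_in_oaa: true}
        analysis:
          class_width: 0.2
          gap: 4
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config()
    for name, sec in (raw.get("species") or {}).items():
        base = cfg.species.get(name)
        growth = GrowthParams(
            linf=float(sec.get("linf_mm", base.growth.linf if base else None)),
            k=float(sec.get("k_per_yr", base.growth.k if base else None)),
            t0=float(sec.get("t0_yr", base.growth.t0 if base else 0.0)),
        )
        banned = bool(sec.get("banned_in_oaa",
                              base.banned_in_oaa if base else False))
        cfg.species[name] = SpeciesConfig(name=name, growth=growth,
                                          banned_in_oaa=banned)
    ana = raw.get("analysis") or {}
    for key, val in ana.items():
        if not hasattr(cfg.analysis, key):
            raise ValueError(f"unknown analysis option {key!r}")
        setattr(cfg.analysis, key, val)
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    doc = {
        "species": {
            name: {
                "linf_mm": sc.growth.linf,
                "k_per_yr": sc.growth.k,
                "t0_yr": sc.growth.t0,
                "banned_in_oaa": sc.banned_in_oaa,
            }
            for name, sc in cfg.species.items()
        },
        "analysis": asdict(cfg.analysis),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
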