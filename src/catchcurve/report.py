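"""Flattening analysis reports into tidy tables and JSON."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .compare import SlopeComparison
from .curves import CatchCurveFit

__all__ = ["jsonify", "report_tables", "write_report"]


def jsonify(obj):
    """Recursively convert report objects to JSON-serializable structures."""
    if isinstance(obj, SlopeComparison):
        d = {
            "design": obj.design, "f": obj.f_stat, "df_num": obj.df_num,
            "df_den": obj.df_den, "p": obj.p,
            "group_fits": {k: jsonify(v) for k, v in obj.group_fits.items()},
        }
        return d
    if isinstance(obj, CatchCurveFit):
        return jsonify(obj.as_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))
             if isinstance(k, tuple) else str(k)): jsonify(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _walk_fits(report: dict):
    """Yield (species, group_label, CatchCurveFit) from any report."""
    for sp, body in report.get("species", {}).items():
        for label, fit in body.get("fits", {}).items():
            yield sp, str(label), fit
        for key, fit in body.get("cell_fits", {}).items():
            yield sp, "|".join(map(str, key)), fit
        for comp in _walk_comparisons_of(body):
            for label, fit in comp[1].group_fits.items():
                yield sp, f"{comp[0]}:{label}", fit


def _walk_comparisons_of(body: dict):
    if isinstance(body.get("ancova"), SlopeComparison):
        yield "ancova", body["ancova"]
    if isinstance(body.get("nested"), SlopeComparison):
        yield "nested", body["nested"]
    for site, sub in body.get("per_site", {}).items():
        yield f"site:{site}", sub["ancova"]
    for ma, sub in body.get("per_ma", {}).items():
        yield f"ma:{ma}", sub["ancova"]


def report_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Tidy CSV-ready tables: fits, comparisons, decomposition."""
    fit_rows = []
    seen = set()
    for sp, label, fit in _walk_fits(report):
        key = (sp, label)
        if key in seen:
            continue
        seen.add(key)
        row = {"analysis": report.get("analysis"), "species": sp, "group": label}
        d = fit.as_dict()
        d.pop("intercept_b", None)
        row.update(d)
        fit_rows.append(row)

    comp_rows = []
    for sp, body in report.get("species", {}).items():
        for term, comp in _walk_comparisons_of(body):
            comp_rows.append({
                "design": comp.design, "species": sp, "term": term,
                "f": comp.f_stat, "df_num": comp.df_num,
                "df_den": comp.df_den, "p": comp.p,
            })
        for holder in ("posthoc",):
            for pair, res in body.get(holder, {}).items():
                comp_rows.append({
                    "design": "posthoc", "species": sp,
                    "term": "|".join(map(str, pair)), "f": res["f"],
                    "df_num": res["df_num"], "df_den": res["df_den"],
                    "p": res["p"],
                })
        if "trend" in body:
            t = body["trend"]
            comp_rows.append({
                "design": "year-trend", "species": sp, "term": "year",
                "f": t["f"], "df_num": t["df_num"], "df_den": t["df_den"],
                "p": t["p"],
            })
    if "species_ttest" in report:
        t = report["species_ttest"]
        comp_rows.append({
            "design": "species-ttest", "species": "|".join(t["species"]),
            "term": "mean_z", "f": t["t"] ** 2, "df_num": 1, "df_den": t["df"],
            "p": t["p"],
        })

    dec_rows = []
    for sp, body in report.get("species", {}).items():
        for regime, dec in body.get("decomposition", {}).items():
            dec_rows.append({
                "species": sp, "regime": regime, "z": dec.z,
                "m_ref": dec.m_ref, "f_est": dec.f_est,
                "pct_vs_ref": dec.pct_vs_ref,
                "below_reference": dec.below_reference,
            })

    return {
        "fits": pd.DataFrame(fit_rows),
        "comparisons": pd.DataFrame(comp_rows),
        "decomposition": pd.DataFrame(dec_rows),
    }


def write_report(report: dict, outdir) -> None:
    """Write fits.csv, comparisons.csv, decomposition.csv and report.json."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report_tables(report)
    tables["fits"].to_csv(outdir / "fits.csv", index=False)
    tables["comparisons"].to_csv(outdir / "comparisons.csv", index=False)
    if len(tables["decomposition"]):
        tables["decomposition"].to_csv(outdir / "decomposition.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(jsonify(report), fh, indent=2, default=str)
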