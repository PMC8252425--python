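"""Group comparisons, significance bands and the end-to-end report bundle.

Comparisons mirror the classical MATLAB-style tests used for this kind
of morphometry: equal-variance two-sample t (Welch by flag), paired t,
and one-way ANOVA.  Significance bands: n.s. for p > .05, * for
p < .05, ** for p < .01, *** for p < .001.  No multiple-testing
correction is applied: pairwise p-values are reported raw alongside the
ANOVA, and downstream users should correct as appropriate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cortimorph import fiber_analysis as fa
from cortimorph import reference_geometry as rg
from cortimorph import yshape_morphometry as ym
from cortimorph.skeleton_io import AnnotationSet

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def significance_band(p: float) -> str:
    """Map a p-value to its significance band (pure function of p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class GroupComparison:
    test: str
    labels: list[str]
    n: list[int]
    mean: list[float]
    sd: list[float]
    statistic: float
    p_value: float
    band: str


def compare_groups(
    samples: dict[str, np.ndarray] | list,
    test: str,
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Compare groups with a named classical test.

    ``samples`` maps label -> 1-D values (ordered dict / list of pairs).
    ``test`` is one of ``two_sample_t`` (two groups), ``paired_t`` (two
    equal-length groups) or ``one_way_anova`` (two or more groups).
    """
    if isinstance(samples, dict):
        items = list(samples.items())
    else:
        items = list(samples)
    labels = [k for k, _ in items]
    values = [np.asarray(v, dtype=float) for _, v in items]
    for label, v in zip(labels, values):
        if v.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 values, has {v.size}")
    if test == "two_sample_t":
        if len(values) != 2:
            raise ValueError("two_sample_t requires exactly two groups")
        res = stats.ttest_ind(
            values[0], values[1], equal_var=equal_var, alternative=alternative
        )
    elif test == "paired_t":
        if len(values) != 2 or values[0].size != values[1].size:
            raise ValueError("paired_t requires two equal-length paired vectors")
        res = stats.ttest_rel(values[0], values[1], alternative=alternative)
    elif test == "one_way_anova":
        res = stats.f_oneway(*values)
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        stat, p = 0.0, 1.0
    return GroupComparison(
        test=test,
        labels=labels,
        n=[int(v.size) for v in values],
        mean=[float(v.mean()) for v in values],
        sd=[float(v.std(ddof=1)) for v in values],
        statistic=stat,
        p_value=p,
        band=significance_band(p),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _row_stats(series_by_row: pd.DataFrame, col: str):
    out = {}
    for row, grp in series_by_row.groupby("row"):
        v = grp[col].astype(float)
        out[f"row{row}"] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else None,
            "n": int(len(v)),
        }
    return out


def run_pipeline(
    annotation: AnnotationSet,
    basal_hint,
    out_dir,
    dc_pitch_um: float = 6.8,
    tc_zone_um: tuple[float, float] = (-22.0, -14.0),
    attach_radius_um: float = 2.0,
) -> dict:
    """Run geometry -> Y-shape -> fiber analyses and write the report bundle.

    Writes per-complex and summary CSVs, fiber and innervation tables
    and ``report.json`` keyed to figure panels (fig1c..fig3d).  Fiber
    stages degrade gracefully: with no contact table the geometry
    report is still produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "qc": {}}

    frame = rg.build_reference_frame(annotation, basal_hint)
    frame.to_json(out / "reference_frame.json")

    measures, table, summary, n_excluded = ym.measure_all_yshapes(annotation, frame)
    table.to_csv(out / "yshapes.csv", index=False)
    if len(summary):
        summary.to_csv(out / "yshapes_summary.csv")
    report["qc"]["yshape_excluded_incomplete"] = n_excluded
    report["qc"]["yshape_flags"] = sorted(
        {f for m in measures for f in m.qc_flags}
    )
    if len(table):
        report["fig1c"] = _row_stats(table, "L_OHC")
        report["fig1d"] = _row_stats(table, "L_PhP")
        report["fig1e"] = _row_stats(table, "L_DC")
        report["fig1f"] = _row_stats(table, "alpha")
        report["fig1g"] = _row_stats(table, "beta_DC")
        report["fig1h"] = {
            "beta_OHC": _row_stats(table, "beta_OHC"),
            "beta_PhP": _row_stats(table, "beta_PhP"),
        }
        report["fig1i"] = {
            f"row{row}": sorted(grp["span"].astype(int).unique().tolist())
            for row, grp in table.groupby("row")
        }
        opc = ym.measure_opc_angles(annotation, frame)
        if len(opc):
            report["fig1h"]["beta_OPC"] = {
                "mean": float(opc["beta_OPC"].mean()),
                "sd": float(opc["beta_OPC"].std(ddof=1)),
                "n": int(len(opc)),
            }

    if not annotation.contacts:
        logger.warning("no contacts available; fiber stages skipped")
        _write_report(report, out)
        return report

    # ---- type-2 SGN afferents ---------------------------------------
    support = fa.build_support_index(
        annotation.trees_of_class("DC") + annotation.trees_of_class("OPC")
    )
    profiles, skipped = [], []
    for fiber in sorted(annotation.trees_of_class("T2SGN"), key=lambda t: t.tree_id):
        try:
            profiles.append(
                fa.build_profile(
                    fiber, annotation.contacts, frame, support, attach_radius_um
                )
            )
        except fa.TurnNotFoundError:
            skipped.append(fiber.tree_id)
    report["qc"]["t2sgn_no_turn"] = skipped
    if profiles:
        pd.concat(
            [p.samples.assign(fiber_id=p.fiber_id) for p in profiles]
        ).to_csv(out / "fiber_profiles.csv", index=False)
    fits = []
    for p in profiles:
        if p.breakpoint_arc is None:
            continue
        try:
            fits.append(fa.fit_biphasic(p, dc_pitch_um))
        except Exception as exc:  # degenerate compartment, reported not fatal
            logger.warning("biphasic fit failed for %s: %s", p.fiber_id, exc)
    if fits:
        climb = np.array([f.climbing_slope for f in fits])
        plateau = np.array([f.contact_slope for f in fits])
        cmp_slopes = compare_groups(
            [("climbing", climb), ("contact", plateau)],
            "paired_t",
            alternative="greater",
        )
        report["fig2e"] = {
            "climbing_slope": {"mean": float(climb.mean()), "sd": float(climb.std(ddof=1)), "n": len(fits)},
            "contact_slope": {"mean": float(plateau.mean()), "sd": float(plateau.std(ddof=1)), "n": len(fits)},
            "climbing_slope_per_dc": {"mean": float(climb.mean() * dc_pitch_um)},
            "contact_slope_per_dc": {"mean": float(plateau.mean() * dc_pitch_um)},
            "paired_t_band": cmp_slopes.band,
        }
    heights = fa.contact_height_stats(profiles)
    heights.to_csv(out / "contact_heights.csv", index=False)
    report["fig2f"] = heights.to_dict(orient="records")
    per_dc = fa.fibers_per_dc(profiles)
    per_dc.to_csv(out / "fibers_per_dc.csv", index=False)
    dcs = per_dc[per_dc["support_class"].str.startswith("DC")]
    report["fig2g"] = {
        cls: {
            "mean": float(grp["n_fibers"].mean()),
            "sd": float(grp["n_fibers"].std(ddof=1)) if len(grp) > 1 else None,
            "n": int(len(grp)),
        }
        for cls, grp in dcs.groupby("support_class")
    }

    aff = fa.InnervationMatrix.from_annotation(annotation, "afferent")
    aff.counts.to_csv(out / "afferent_matrix.csv")
    per_ohc, per_row, ribbon = fa.afferent_counts(aff)
    report["fig2h"] = {
        f"row{r}": {"mean": float(v["mean"]), "sd": float(v["std"]), "n": int(v["count"])}
        for r, v in per_row.iterrows()
    }
    report["ribbon_fraction"] = {f"row{r}": float(v) for r, v in ribbon.items()}
    spec_table, spec_summary = fa.row_specificity(aff)
    spec_table.to_csv(out / "afferent_specificity.csv", index=False)
    report["fig2i"] = spec_summary

    # ---- MOC efferents ----------------------------------------------
    zone = fa.TunnelZone.from_frame(frame, *tc_zone_um)
    classes, flagged = fa.classify_all_moc(annotation, zone)
    report["qc"]["moc_unclassifiable"] = flagged
    if classes:
        eff = fa.InnervationMatrix.from_annotation(annotation, "efferent")
        eff.counts.to_csv(out / "efferent_matrix.csv")
        per_ohc_e, per_row_e, subtype_stats, row_dist = fa.efferent_counts(eff, classes)
        pd.DataFrame(
            [
                {"fiber_id": c.fiber_id, "n_tunnel_crossings": c.n_tunnel_crossings,
                 "subtype": c.subtype, "n_synapses": c.n_synapses}
                for c in classes
            ]
        ).to_csv(out / "moc_classes.csv", index=False)
        n_branched = sum(c.subtype == "branched" for c in classes)
        report["fig3c"] = {
            f"row{r}": {"mean": float(v["mean"]), "sd": float(v["std"]), "n": int(v["count"])}
            for r, v in per_row_e.iterrows()
        }
        report["fig3d"] = {
            "n_fibers": len(classes),
            "n_branched": int(n_branched),
            "branched_fraction": n_branched / len(classes),
            "subtype_synapses": subtype_stats.to_dict(orient="records"),
            "row_distribution": row_dist.to_dict(orient="records"),
        }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
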