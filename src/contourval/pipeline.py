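"""Variability and timing analyses over a complete study manifest.

Four analyses are orchestrated here:

* **intra-observer**: for each (structure, subject, rater), DSC and MDA
  between the two sessions of one method — how repeatable each observer
  is with themselves (30 index pairs per structure for the default
  6-subject x 5-rater design);
* **inter-observer**: for each (structure, subject) of one (method,
  session) set, a STAPLE consensus of all raters' masks is the shared
  reference, and each rater is scored against it;
* **method comparison**: per structure and metric, a normality-gated
  paired location test of M vs AM indices (paired by structure, subject
  and rater), the AM/M IQR ratio, and boxplot summaries with 5th/95th
  percentile whiskers (including the 95th percentile of MDA, the
  clinically quoted tail);
* **timing**: manual-contouring vs editing times.  Femoral head times are
  summed into a single merged ROI per (subject, rater, method, session)
  before any averaging.  Time saving is |T_M − T_AM| / T_M, reported as
  an integer percent (rounded half away from zero); per-rater rows
  average the whole-pelvis time (sum over timing ROIs) over subjects and
  sessions, per-ROI rows average over raters, subjects and sessions.
  Timing consistency is probed with 16 paired t-tests on the 30-element
  (rater x subject) time vectors: session 1 vs session 2 within each
  method, and M vs AM within each session, for each of the 4 timing ROIs.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .io_model import StudyManifest
from .metrics import similarity
from .staple import StapleConfig, build_reference
from .stats import (
    DEFAULT_ALPHA,
    boxplot_summary,
    iqr_ratio,
    paired_location_test,
    paired_t,
)

__all__ = [
    "intra_observer_indices",
    "inter_observer_indices",
    "compare_methods",
    "timing_summary",
    "timing_tests",
    "roi_times",
    "round_half_away",
]

INDEX_COLUMNS = ("structure", "subject_id", "rater_id", "method",
                 "comparison", "dsc", "mda_mm")


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero
    (45.5 -> 46, -45.5 -> -46); used for reported percent savings."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


# ---------------------------------------------------------------------------
# Similarity index tables
# ---------------------------------------------------------------------------

def intra_observer_indices(manifest: StudyManifest, method: str) -> pd.DataFrame:
    """Session-1 vs session-2 DSC/MDA per (structure, subject, rater)."""
    design = manifest.design
    rows = []
    for structure in design.structures:
        for sub in design.subjects:
            for rat in design.raters:
                r1 = manifest.record(sub, rat, structure, method, 1)
                r2 = manifest.record(sub, rat, structure, method, 2)
                m1, m2 = manifest.get_mask(r1), manifest.get_mask(r2)
                try:
                    sim = similarity(m1, m2)
                except ValueError as exc:
                    raise ValueError(
                        f"intra-observer comparison failed for (subject={sub}, "
                        f"rater={rat}, structure={structure}, method={method}): {exc}"
                    ) from exc
                rows.append((structure, sub, rat, method,
                             f"{method}1_vs_{method}2", sim.dsc, sim.mda_mm))
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def inter_observer_indices(manifest: StudyManifest, method: str, session: int,
                           staple_cfg: StapleConfig = StapleConfig()
                           ) -> pd.DataFrame:
    """Each rater vs the per-(structure, subject) STAPLE reference of one
    (method, session) contour set."""
    design = manifest.design
    if len(design.raters) < 2:
        raise ValueError("inter-observer analysis needs at least 2 raters")
    tag = f"{method}{session}_vs_Ref_{method}{session}"
    rows = []
    for structure in design.structures:
        for sub in design.subjects:
            masks = {
                rat: manifest.get_mask(
                    manifest.record(sub, rat, structure, method, session))
                for rat in design.raters
            }
            try:
                ref = build_reference(masks, staple_cfg)
            except (ValueError, FloatingPointError) as exc:
                raise ValueError(
                    f"STAPLE reference failed for (subject={sub}, "
                    f"structure={structure}, method={method}, "
                    f"session={session}): {exc}"
                ) from exc
            for rat in design.raters:
                sim = similarity(masks[rat], ref)
                rows.append((structure, sub, rat, method, tag,
                             sim.dsc, sim.mda_mm))
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


# ---------------------------------------------------------------------------
# M vs AM comparison of index tables
# ---------------------------------------------------------------------------

_JOIN_KEYS = ["structure", "subject_id", "rater_id"]


def compare_methods(m_table: pd.DataFrame, am_table: pd.DataFrame,
                    alpha: float = DEFAULT_ALPHA) -> dict:
    """Per-structure statistical comparison of M and AM index tables.

    Tables are joined on (structure, subject, rater) — row order is
    irrelevant.  For each structure and metric the report holds the
    normality-gated paired test (differences AM − M), the AM/M IQR
    ratio, and boxplot summaries of both groups.  Degenerate inputs
    (all-zero differences) are surfaced per structure, not raised.
    """
    merged = m_table.merge(am_table, on=_JOIN_KEYS, suffixes=("_m", "_am"))
    if len(merged) != len(m_table) or len(merged) != len(am_table):
        raise ValueError(
            "index tables are misaligned: M and AM rows do not pair 1:1 "
            "on (structure, subject, rater)"
        )
    report: dict = {"alpha": alpha, "structures": {}, "n_tests": 0}
    for structure, grp in merged.groupby("structure", sort=True):
        entry: dict = {}
        for metric in ("dsc", "mda_mm"):
            am = grp[f"{metric}_am"].to_numpy()
            m = grp[f"{metric}_m"].to_numpy()
            metric_entry: dict = {
                "boxplot_am": asdict(boxplot_summary(am)),
                "boxplot_m": asdict(boxplot_summary(m)),
            }
            try:
                test = paired_location_test(am, m, alpha=alpha,
                                            label=f"{structure}/{metric}")
                metric_entry["test"] = asdict(test)
                report["n_tests"] += 1
            except ValueError as exc:
                metric_entry["error"] = str(exc)
            try:
                metric_entry["iqr_ratio_am_over_m"] = iqr_ratio(am, m)
            except ValueError as exc:
                metric_entry["iqr_ratio_error"] = str(exc)
            entry[metric] = metric_entry
        entry["mda_p95_am"] = float(np.quantile(grp["mda_mm_am"], 0.95))
        entry["mda_p95_m"] = float(np.quantile(grp["mda_mm_m"], 0.95))
        report["structures"][structure] = entry
    return report


# ---------------------------------------------------------------------------
# Timing
# ---------------------------------------------------------------------------

def roi_times(manifest: StudyManifest) -> pd.DataFrame:
    """Long table (subject, rater, roi, method, session, time_min) with the
    femoral heads summed into the merged timing ROI."""
    design = manifest.design
    rows = [
        (r.subject_id, r.rater_id, design.timing_roi_of(r.structure),
         r.method, r.session, r.time_min)
        for r in manifest.records
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "rater_id", "roi",
                                     "method", "session", "time_min"])
    return (df.groupby(["subject_id", "rater_id", "roi", "method", "session"],
                       as_index=False)["time_min"].sum())


def _saving_row(scope: str, identifier: str, t_m: float, t_am: float) -> dict:
    if t_m <= 0:
        raise ValueError(f"nonpositive manual time for {scope} {identifier!r}")
    abs_saving = abs(t_m - t_am)
    pct_raw = 100.0 * abs_saving / t_m
    return {"scope": scope, "identifier": identifier,
            "t_m_min": t_m, "t_am_min": t_am,
            "abs_saving_min": abs_saving,
            "pct_saving_raw": pct_raw,
            "pct_saving": round_half_away(pct_raw)}


def timing_summary(manifest: StudyManifest) -> pd.DataFrame:
    """Per-rater, per-ROI and whole-pelvis time savings.

    Per-rater rows average the whole-pelvis time (sum of timing-ROI
    times) over subjects and sessions; per-ROI rows average over raters,
    subjects and sessions; the Pelvis row averages whole-pelvis times
    over everything.
    """
    times = roi_times(manifest)
    design = manifest.design
    pelvis = (times.groupby(["subject_id", "rater_id", "method", "session"],
                            as_index=False)["time_min"].sum())
    rows = []
    for rat in design.raters:
        sub = pelvis[pelvis["rater_id"] == rat]
        t_m = sub.loc[sub["method"] == "M", "time_min"].mean()
        t_am = sub.loc[sub["method"] == "AM", "time_min"].mean()
        rows.append(_saving_row("rater", rat, t_m, t_am))
    for roi in design.timing_rois:
        sub = times[times["roi"] == roi]
        t_m = sub.loc[sub["method"] == "M", "time_min"].mean()
        t_am = sub.loc[sub["method"] == "AM", "time_min"].mean()
        rows.append(_saving_row("roi", roi, t_m, t_am))
    t_m = pelvis.loc[pelvis["method"] == "M", "time_min"].mean()
    t_am = pelvis.loc[pelvis["method"] == "AM", "time_min"].mean()
    rows.append(_saving_row("pelvis", "Pelvis", t_m, t_am))
    return pd.DataFrame(rows)


_TIMING_CONTRASTS = (
    ("M1_vs_M2", ("M", 1), ("M", 2)),
    ("AM1_vs_AM2", ("AM", 1), ("AM", 2)),
    ("M1_vs_AM1", ("M", 1), ("AM", 1)),
    ("M2_vs_AM2", ("M", 2), ("AM", 2)),
)


def timing_tests(manifest: StudyManifest) -> list[dict]:
    """16 paired t-tests on (rater x subject) time vectors: per timing ROI,
    session consistency within each method and M-vs-AM within each
    session.  Degenerate contrasts (zero-variance differences) are
    flagged, not raised."""
    times = roi_times(manifest)
    design = manifest.design
    pivot = times.set_index(["roi", "method", "session", "rater_id",
                             "subject_id"])["time_min"].sort_index()
    cell_index = pd.MultiIndex.from_product(
        [design.raters, design.subjects], names=["rater_id", "subject_id"])
    results: list[dict] = []
    for roi in design.timing_rois:
        for name, (me_a, se_a), (me_b, se_b) in _TIMING_CONTRASTS:
            a = pivot.loc[(roi, me_a, se_a)].reindex(cell_index).to_numpy()
            b = pivot.loc[(roi, me_b, se_b)].reindex(cell_index).to_numpy()
            label = f"{roi}:{name}"
            entry: dict = {"label": label, "roi": roi, "contrast": name,
                           "n": len(a)}
            try:
                stat, p = paired_t(a - b)
                entry.update({"test_name": "paired_t", "statistic": stat,
                              "p_value": p})
            except ValueError as exc:
                entry["error"] = str(exc)
            results.append(entry)
    return results
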