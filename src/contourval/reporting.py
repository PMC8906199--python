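"""Study orchestration and report rendering.

``run_all`` wires a validated manifest (and optionally a decisions file)
through every analysis — intra-observer for M and AM, inter-observer for
all four contour sets, the M-vs-AM method comparison, timing summary and
consistency tests, and the blind-review bias analysis — and writes one
machine-readable artifact per analysis plus a run report.  Outputs are
deterministic given the inputs and configuration: rerunning produces
byte-identical files.

Machine outputs keep full precision; ``render_summary`` produces the
human-readable tables with display rounding (integer percents,
2-decimal p-values).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import bias_analysis, load_decisions_csv
from .io_model import StudyManifest
from .pipeline import (
    compare_methods,
    intra_observer_indices,
    inter_observer_indices,
    timing_summary,
    timing_tests,
)
from .staple import StapleConfig

__all__ = ["run_all", "render_summary"]

logger = logging.getLogger("contourval")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(manifest: StudyManifest, out_dir: str | Path,
            decisions_csv: str | Path | None = None,
            staple_cfg: StapleConfig = StapleConfig(),
            alpha: float = 0.05) -> dict:
    """Run every analysis on a complete study and write all outputs.

    Returns the run report (also written as ``run_report.json``).  A
    missing decisions file downgrades the bias analysis to a warning;
    any other failure propagates with its cell identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"tool": "contourval", "version": __version__,
                    "alpha": alpha,
                    "staple_config": vars(staple_cfg).copy(),
                    "design": {
                        "subjects": list(manifest.design.subjects),
                        "raters": list(manifest.design.raters),
                        "structures": list(manifest.design.structures),
                        "timing_rois": list(manifest.design.timing_rois),
                    },
                    "outputs": {}, "counts": {}, "warnings": []}

    logger.info("intra-observer analysis (M, AM)")
    intra = {m: intra_observer_indices(manifest, m) for m in ("M", "AM")}
    intra_df = pd.concat(intra.values(), ignore_index=True)
    intra_path = out / "intra_indices.csv"
    intra_df.to_csv(intra_path, index=False)
    report["outputs"]["intra_indices"] = intra_path.name
    report["counts"]["intra_tables"] = len(intra)
    report["counts"]["intra_rows"] = len(intra_df)

    logger.info("inter-observer analysis (M1, M2, AM1, AM2)")
    inter = {
        f"{m}{s}": inter_observer_indices(manifest, m, s, staple_cfg)
        for m in ("M", "AM") for s in (1, 2)
    }
    inter_df = pd.concat(inter.values(), ignore_index=True)
    inter_path = out / "inter_indices.csv"
    inter_df.to_csv(inter_path, index=False)
    report["outputs"]["inter_indices"] = inter_path.name
    report["counts"]["inter_tables"] = len(inter)
    report["counts"]["inter_rows"] = len(inter_df)

    logger.info("M vs AM method comparison")
    comparison = {
        "intra": compare_methods(intra["M"], intra["AM"], alpha),
        "inter_session1": compare_methods(inter["M1"], inter["AM1"], alpha),
        "inter_session2": compare_methods(inter["M2"], inter["AM2"], alpha),
    }
    comp_path = out / "method_comparison.json"
    _dump_json(comparison, comp_path)
    report["outputs"]["method_comparison"] = comp_path.name
    n_tests = sum(c["n_tests"] for c in comparison.values())

    logger.info("timing analysis")
    tsum = timing_summary(manifest)
    tsum_path = out / "timing_summary.csv"
    tsum.to_csv(tsum_path, index=False)
    report["outputs"]["timing_summary"] = tsum_path.name
    ttests = timing_tests(manifest)
    ttests_path = out / "timing_tests.json"
    _dump_json(ttests, ttests_path)
    report["outputs"]["timing_tests"] = ttests_path.name
    report["counts"]["timing_tests"] = len(ttests)
    degenerate = [t["label"] for t in ttests if "error" in t]
    if degenerate:
        report["warnings"].append(
            f"degenerate timing tests: {', '.join(degenerate)}")
    n_tests += sum(1 for t in ttests if "error" not in t)

    if decisions_csv is not None and Path(decisions_csv).exists():
        logger.info("bias analysis")
        bias = bias_analysis(load_decisions_csv(decisions_csv))
        bias_path = out / "bias_report.json"
        _dump_json(bias, bias_path)
        report["outputs"]["bias_report"] = bias_path.name
        report["counts"]["bias_tables"] = 1
        n_tests += 1
    else:
        report["counts"]["bias_tables"] = 0
        report["warnings"].append(
            "decisions file missing; bias analysis skipped")
        logger.warning("decisions file missing; bias analysis skipped")

    report["counts"]["statistical_tests"] = n_tests
    _dump_json(report, out / "run_report.json")
    report["outputs"]["run_report"] = "run_report.json"
    return report


# ---------------------------------------------------------------------------
# Human-readable rendering
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def render_summary(out_dir: str | Path) -> str:
    """Render the written outputs as aligned text tables: the timing table
    (ROI rows plus Pelvis, integer percents), the paired contingency
    table, and per-structure metric summaries with 5th/95th whiskers."""
    out = Path(out_dir)
    lines: list[str] = []

    tsum_path = out / "timing_summary.csv"
    if tsum_path.exists():
        tsum = pd.read_csv(tsum_path)
        lines.append("Timing: contouring (M) vs editing (AM), minutes")
        lines.append(f"{'':<16}{'T_M':>8}{'T_AM':>8}{'|diff|':>8}{'saving':>8}")
        shown = tsum[tsum["scope"].isin(["roi", "pelvis"])]
        for _, row in shown.iterrows():
            lines.append(
                f"{row['identifier']:<16}{row['t_m_min']:>8.1f}"
                f"{row['t_am_min']:>8.1f}{row['abs_saving_min']:>8.1f}"
                f"{row['pct_saving']:>7.0f}%"
            )
        lines.append("")

    bias_path = out / "bias_report.json"
    if bias_path.exists():
        with open(bias_path, encoding="utf-8") as fh:
            bias = json.load(fh)
        t = bias["table"]
        lines.append("Blind-review contingency (rows AM, columns M)")
        lines.append(f"{'':<6}{'NO':>6}{'YES':>6}")
        lines.append(f"{'NO':<6}{t['n_nn']:>6}{t['n_ny']:>6}")
        lines.append(f"{'YES':<6}{t['n_yn']:>6}{t['n_yy']:>6}")
        lines.append(f"McNemar exact p = {_fmt_p(bias['p_exact'])}"
                     + (f", chi2(cc) p = {_fmt_p(bias['p_chi2_cc'])}"
                        if bias["p_chi2_cc"] is not None else ""))
        lines.append("")

    comp_path = out / "method_comparison.json"
    if comp_path.exists():
        with open(comp_path, encoding="utf-8") as fh:
            comparison = json.load(fh)
        for comp_name, comp in sorted(comparison.items()):
            lines.append(f"M vs AM ({comp_name}); whiskers = 5th-95th percentile")
            for structure, entry in sorted(comp["structures"].items()):
                for metric in ("dsc", "mda_mm"):
                    me = entry[metric]
                    bm, ba = me["boxplot_m"], me["boxplot_am"]
                    detail = (f"p = {_fmt_p(me['test']['p_value'])} "
                              f"({me['test']['test_name']})"
                              if "test" in me else f"[{me['error']}]")
                    lines.append(
                        f"  {structure:<16}{metric:<8}"
                        f"M {bm['median']:.3f} [{bm['p5']:.3f}, {bm['p95']:.3f}]  "
                        f"AM {ba['median']:.3f} [{ba['p5']:.3f}, {ba['p95']:.3f}]  "
                        + detail
                    )
            lines.append("")
    return "\n".join(lines)
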