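"""Blind-review bias analysis.

In the blind acceptance test, observers judge shuffled, anonymized
contours — accept (YES) or flag for correction (NO) — without knowing
whether each contour was drawn manually (M) or auto-generated and edited
(AM).  Pairing each observer's M and AM judgments of the same subject and
region of interest gives a matched 2x2 table whose discordant cells feed
McNemar's test of the null hypothesis that observers are not influenced
by how a contour was produced.

Judgments marked CONFUSING are excluded from the analysis, as is any
(rater, subject, roi) whose M or AM decision is missing; exclusions are
counted and identified in the report.  Distractor rows — duplicate
contours inserted into the blind review as a consistency device — are
ignored entirely.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .stats import ContingencyTable2x2, mcnemar

__all__ = [
    "DecisionRecord",
    "build_contingency",
    "bias_analysis",
    "load_decisions_csv",
    "write_decisions_csv",
]

_DECISIONS = ("YES", "NO", "CONFUSING")
DECISIONS_COLUMNS = ("rater_id", "subject_id", "roi", "method", "decision",
                     "distractor")


@dataclass(frozen=True)
class DecisionRecord:
    """One blind accept/reject judgment of one contour."""

    rater_id: str
    subject_id: str
    roi: str
    method: str          # "M" | "AM"
    decision: str        # "YES" | "NO" | "CONFUSING"
    distractor: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("M", "AM"):
            raise ValueError(f"method must be M or AM, got {self.method!r}")
        if self.decision not in _DECISIONS:
            raise ValueError(
                f"decision must be one of {_DECISIONS}, got {self.decision!r}"
            )

    @property
    def pair_key(self) -> tuple[str, str, str]:
        return (self.rater_id, self.subject_id, self.roi)


def _pair_decisions(decisions: Sequence[DecisionRecord]
                    ) -> tuple[list[tuple[str, str]], list[dict]]:
    """Group decisions into complete (AM, M) pairs.

    Returns (pairs, exclusions): each pair is the (AM decision, M decision)
    of one (rater, subject, roi); exclusions identify incomplete or
    CONFUSING cells.  Duplicate decisions for a cell are an error.
    """
    by_cell: dict[tuple[str, str, str], dict[str, str]] = {}
    for rec in decisions:
        if rec.distractor:
            continue
        cell = by_cell.setdefault(rec.pair_key, {})
        if rec.method in cell:
            raise ValueError(
                f"duplicate {rec.method} decision for (rater={rec.rater_id}, "
                f"subject={rec.subject_id}, roi={rec.roi})"
            )
        cell[rec.method] = rec.decision

    pairs: list[tuple[str, str]] = []
    exclusions: list[dict] = []
    for key in sorted(by_cell):
        cell = by_cell[key]
        rater, subject, roi = key
        ident = {"rater_id": rater, "subject_id": subject, "roi": roi}
        if "M" not in cell or "AM" not in cell:
            exclusions.append({**ident, "reason": "incomplete_pair"})
        elif "CONFUSING" in (cell["M"], cell["AM"]):
            exclusions.append({**ident, "reason": "confusing"})
        else:
            pairs.append((cell["AM"], cell["M"]))
    return pairs, exclusions


def build_contingency(decisions: Sequence[DecisionRecord]) -> ContingencyTable2x2:
    """Paired 2x2 table of blind decisions, rows = AM decision, columns =
    M decision; CONFUSING and incomplete pairs are dropped."""
    pairs, _ = _pair_decisions(decisions)
    counts = {"nn": 0, "ny": 0, "yn": 0, "yy": 0}
    for am_dec, m_dec in pairs:
        key = ("n" if am_dec == "NO" else "y") + ("n" if m_dec == "NO" else "y")
        counts[key] += 1
    return ContingencyTable2x2(counts["nn"], counts["ny"], counts["yn"],
                               counts["yy"])


def bias_analysis(decisions: Sequence[DecisionRecord]) -> dict:
    """Full bias report: contingency cells, exact and continuity-corrected
    McNemar p-values, per-method acceptance rates, exclusion accounting."""
    pairs, exclusions = _pair_decisions(decisions)
    if not pairs:
        raise ValueError("no complete decision pairs; bias analysis undefined")
    table = build_contingency(decisions)
    b, c = table.discordant
    p_chi2 = mcnemar(table, "chi2_cc") if (b + c) > 0 else None
    n = table.total
    return {
        "table": {"n_nn": table.n_nn, "n_ny": table.n_ny,
                  "n_yn": table.n_yn, "n_yy": table.n_yy},
        "n_pairs": n,
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "p_exact": mcnemar(table, "exact"),
        "p_chi2_cc": p_chi2,
        "acceptance_rate_am": (table.n_yn + table.n_yy) / n,
        "acceptance_rate_m": (table.n_ny + table.n_yy) / n,
    }


# ---------------------------------------------------------------------------
# Decisions CSV
# ---------------------------------------------------------------------------

def load_decisions_csv(path: str | Path) -> list[DecisionRecord]:
    """Read a decisions CSV with columns
    ``rater_id,subject_id,roi,method,decision,distractor``."""
    records: list[DecisionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(DECISIONS_COLUMNS):
            raise ValueError(
                f"decisions header must be exactly {','.join(DECISIONS_COLUMNS)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            records.append(DecisionRecord(
                rater_id=row["rater_id"],
                subject_id=row["subject_id"],
                roi=row["roi"],
                method=row["method"],
                decision=row["decision"],
                distractor=row["distractor"].strip().lower() in ("1", "true", "yes"),
            ))
    return records


def write_decisions_csv(records: Iterable[DecisionRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DECISIONS_COLUMNS)
        for r in records:
            writer.writerow([r.rater_id, r.subject_id, r.roi, r.method,
                             r.decision, "true" if r.distractor else "false"])
    return path
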