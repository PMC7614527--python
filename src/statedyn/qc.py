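"""Motion / data-quality exclusion of scans prior to modelling.

Scans are excluded when ANY active quality index strictly exceeds its upper
bound ("above threshold" reads as strictly above, so boundary scans are
kept).  The indices are per-scan summaries computed upstream of this
package: maximum spike percentage, maximum framewise displacement (mm),
maximum DVARS (spatial SD of successive volume differences), and mean
framewise displacement.  Mean-FD filtering is off by default and intended
for sensitivity re-runs.  Default numeric bounds are placeholders: the
thresholds in use at a given centre are a configuration input, not a claim
of this package.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

import pandas as pd

__all__ = [
    "MotionIndices",
    "QCThresholds",
    "filter_scans",
    "apply_qc",
    "select_scan",
]

MOTION_COLUMNS = (
    "max_spike_percentage",
    "max_framewise_displacement",
    "max_dvars",
    "mean_framewise_displacement",
)


@dataclass(frozen=True)
class MotionIndices:
    max_spike_percentage: float
    max_framewise_displacement: float
    max_dvars: float
    mean_framewise_displacement: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"motion index {f.name} is negative ({v})")


@dataclass(frozen=True)
class QCThresholds:
    """Upper bounds per motion index; ``None`` deactivates an index.

    The shipped defaults are placeholder magnitudes for synthetic data, not
    published thresholds.  ``mean_framewise_displacement`` is inactive by
    default (supplementary-style sensitivity analyses switch it on).
    """

    max_spike_percentage: float | None = 5.0
    max_framewise_displacement: float | None = 3.0
    max_dvars: float | None = 5.0
    mean_framewise_displacement: float | None = field(default=None)

    def active(self) -> dict[str, float]:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                if v <= 0:
                    raise ValueError(f"active threshold {f.name} must be positive")
                out[f.name] = float(v)
        if not out:
            raise ValueError("no active QC thresholds")
        return out


def filter_scans(
    scans: list[tuple[str, MotionIndices]], thresholds: QCThresholds
) -> tuple[list[str], list[tuple[str, list[str]]]]:
    """Partition scans into (kept ids, excluded ids with violated indices).

    A scan is excluded iff any active index strictly exceeds its bound;
    the reasons list names every violated index.
    """
    bounds = thresholds.active()
    kept: list[str] = []
    excluded: list[tuple[str, list[str]]] = []
    for scan_id, idx in scans:
        reasons = [name for name, bound in bounds.items() if getattr(idx, name) > bound]
        if reasons:
            excluded.append((scan_id, reasons))
        else:
            kept.append(scan_id)
    return kept, excluded


def apply_qc(cohort: pd.DataFrame, thresholds: QCThresholds) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a scan-level cohort table with a ``qc_pass`` column.

    Returns (cohort with qc_pass, exclusions table with one row per excluded
    scan listing the violated indices, comma-separated).
    """
    scans = [
        (
            str(row["scan_id"]),
            MotionIndices(**{c: float(row[c]) for c in MOTION_COLUMNS if c in cohort.columns}),
        )
        for _, row in cohort.iterrows()
    ]
    kept, excluded = filter_scans(scans, thresholds)
    kept_set = set(kept)
    out = cohort.copy()
    out["qc_pass"] = out["scan_id"].astype(str).map(lambda s: s in kept_set)
    excl = pd.DataFrame(
        [(sid, ",".join(reasons)) for sid, reasons in excluded],
        columns=["scan_id", "violated_indices"],
    )
    return out, excl


def select_scan(cohort: pd.DataFrame, which: str = "latest") -> pd.DataFrame:
    """Pick one scan per subject among scans passing QC.

    ``which='latest'`` keeps the subject's latest passing scan (cross-sectional
    convention, maximizing per-participant volume counts); ``'earliest'`` keeps
    the first passing scan (the baseline convention for longitudinal
    prediction).  Recency is ordered by ``visit_index``; ties break by larger
    ``n_volumes``, then lexicographically smaller ``scan_id``.
    """
    if which not in ("latest", "earliest"):
        raise ValueError("which must be 'latest' or 'earliest'")
    df = cohort[cohort["qc_pass"]].copy() if "qc_pass" in cohort.columns else cohort.copy()
    asc_visit = which == "earliest"
    df = df.sort_values(
        by=["visit_index", "n_volumes", "scan_id"],
        ascending=[asc_visit, False, True],
        kind="mergesort",
    )
    return df.groupby("subject_id", sort=True).head(1).reset_index(drop=True)
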