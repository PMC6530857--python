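"""File round-trips: cohort / comparator / panel CSVs, sweep tables, manifests.

All tabular I/O is comma-separated UTF-8 with a mandatory header row and
``.`` decimals, fixed to avoid locale drift.  Manifests are JSON with
sorted keys so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .engine import SweepResult
from .noise import ComparatorLabels
from .panel import PanelAssessment, normalize_call

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_comparator_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_panel_report",
    "write_sweep_csv",
    "write_manifest",
    "parse_grid",
]

PathLike = Union[str, Path]


def write_cohort_csv(cohort: Cohort, path: PathLike) -> None:
    """Write `id,truth,score[,call]` with 0/1 labels."""
    df = pd.DataFrame(
        {
            "id": cohort.ids,
            "truth": cohort.truth.astype(int),
            "score": cohort.score,
        }
    )
    if cohort.call is not None:
        df["call"] = cohort.call.astype(int)
    df.to_csv(path, index=False)


def read_cohort_csv(path: PathLike, threshold: Optional[float] = None) -> Cohort:
    """Read a cohort CSV; a missing `call` column requires a threshold."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "truth", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} is missing columns: {sorted(missing)}")
    call = None
    if "call" in df.columns:
        call = df["call"].astype(int).astype(bool).to_numpy()
    elif threshold is None:
        raise ValueError(
            f"cohort CSV {path} has no 'call' column and no threshold was supplied"
        )
    return Cohort(
        ids=df["id"].to_numpy(dtype=object),
        truth=df["truth"].astype(int).astype(bool).to_numpy(),
        score=df["score"].astype(float).to_numpy(),
        call=call,
        threshold=threshold,
    )


def write_comparator_csv(
    cohort: Cohort, comparator: ComparatorLabels, path: PathLike
) -> None:
    pd.DataFrame(
        {
            "id": cohort.ids,
            "comparator": comparator.labels.astype(int),
            "flipped": comparator.flipped.astype(int),
        }
    ).to_csv(path, index=False)


def write_panel_csv(assessments: Sequence[PanelAssessment], path: PathLike) -> None:
    pd.DataFrame(
        {
            "id": [a.patient_id for a in assessments],
            "panelist1": [a.calls[0] for a in assessments],
            "panelist2": [a.calls[1] for a in assessments],
            "panelist3": [a.calls[2] for a in assessments],
            "site_dx": [a.site_dx if a.site_dx is not None else "NA" for a in assessments],
        }
    ).to_csv(path, index=False)


def read_panel_csv(path: PathLike) -> List[PanelAssessment]:
    """Parse a panel CSV, reporting every malformed row by line number.

    Rows are never dropped silently: any invalid call token raises a single
    error listing all offending data lines (header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"id", "panelist1", "panelist2", "panelist3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV {path} is missing columns: {sorted(missing)}")
    out: List[PanelAssessment] = []
    bad: List[int] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header occupies line 1
        try:
            calls = tuple(
                normalize_call(row[c]) for c in ("panelist1", "panelist2", "panelist3")
            )
            site = row.get("site_dx")
            if site is None or pd.isna(site) or str(site).strip().upper() == "NA":
                site_dx = None
            else:
                site_dx = normalize_call(site)
            out.append(
                PanelAssessment(patient_id=str(row["id"]), calls=calls, site_dx=site_dx)
            )
        except ValueError:
            bad.append(lineno)
    if bad:
        raise ValueError(
            f"panel CSV {path} has invalid call tokens on line(s): {bad}"
        )
    return out


def write_panel_report(
    assessments: Sequence[PanelAssessment], path: PathLike
) -> pd.DataFrame:
    """Per-patient confidence/assignment/stratum table; also returned."""
    df = pd.DataFrame(
        {
            "id": [a.patient_id for a in assessments],
            "panelist1": [a.calls[0] for a in assessments],
            "panelist2": [a.calls[1] for a in assessments],
            "panelist3": [a.calls[2] for a in assessments],
            "site_dx": [a.site_dx if a.site_dx is not None else "NA" for a in assessments],
            "confidence": [a.confidence for a in assessments],
            "assigned": [a.assigned for a in assessments],
            "stratum": [a.stratum for a in assessments],
            "p_wrong": [a.p_wrong for a in assessments],
        }
    )
    df.to_csv(path, index=False)
    return df


def write_sweep_csv(result: SweepResult, path: PathLike) -> None:
    cols = ["level", "metric", "median", "ci_lower", "ci_upper", "n_missing"]
    result.table[cols].to_csv(path, index=False)


def write_manifest(params: dict, path: PathLike) -> None:
    """JSON run manifest with sorted keys; captures every parameter and seed."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def parse_grid(text: str) -> List[float]:
    """Parse `start:stop:step` (inclusive both ends, tolerance 1e-9) or a single number.

    Also accepts a comma-separated list of numbers.
    """
    text = text.strip()
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid must be start:stop:step, got {text!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0 or stop < start:
            raise ValueError(f"grid {text!r} must have step > 0 and stop >= start")
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return [start + i * step for i in range(n)]
    if "," in text:
        return [float(p) for p in text.split(",") if p.strip()]
    return [float(text)]
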