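"""Docking-score ingestion and top-fraction retention.

Docking scores (kcal/mol, more negative = better) are produced externally
and consumed here as CSV.  The second reductive filter keeps the best
``ceil(fraction * N)`` non-control compounds and then adds back every
control (known-inhibitor) compound regardless of its score, mirroring the
"retain top 50% and add known inhibitors" pool construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("hopscreen")

__all__ = ["DockScore", "read_dock_scores", "write_dock_scores", "retain_top_fraction"]


@dataclass(frozen=True)
class DockScore:
    compound_id: str
    score: float  # kcal/mol; more negative = better
    source: str = "external"


def read_dock_scores(path: str | Path) -> list[DockScore]:
    """Read a docking-score CSV with columns ``compound_id, score[, source]``.

    Non-numeric scores are rejected row-by-row with a logged row index;
    a duplicated compound_id is a fatal error naming the offender.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if not {"compound_id", "score"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns compound_id, score")
    records: list[DockScore] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        score = pd.to_numeric(row["score"], errors="coerce")
        if pd.isna(score) or not math.isfinite(score):
            logger.warning("%s: rejecting non-numeric score at row %d", path, idx)
            continue
        cid = str(row["compound_id"])
        if cid in seen:
            raise ValueError(f"{path}: duplicate compound_id {cid!r}")
        seen.add(cid)
        source = str(row["source"]) if "source" in df.columns and not pd.isna(row.get("source")) else "external"
        records.append(DockScore(cid, float(score), source))
    return records


def write_dock_scores(scores: Sequence[DockScore], path: str | Path, retained: set[str] | None = None) -> None:
    rows = [
        {
            "compound_id": s.compound_id,
            "score": s.score,
            "source": s.source,
            **({"retained": s.compound_id in retained} if retained is not None else {}),
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def retain_top_fraction(
    scores: Sequence[DockScore],
    fraction: float,
    controls: Iterable[str] = (),
) -> list[DockScore]:
    """Keep the best ``ceil(fraction * N)`` non-control scores plus all controls.

    N counts non-control compounds; ties on score break by compound_id
    (lexicographic), so the selection is stable and deterministic.  Controls
    present in the input are always retained, whatever their score.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    control_set = set(controls)
    pool = [s for s in scores if s.compound_id not in control_set]
    kept_controls = [s for s in scores if s.compound_id in control_set]
    n_keep = math.ceil(fraction * len(pool))
    ranked = sorted(pool, key=lambda s: (s.score, s.compound_id))
    retained = ranked[:n_keep] + kept_controls
    # restore input order for stability
    order = {s.compound_id: i for i, s in enumerate(scores)}
    retained.sort(key=lambda s: order[s.compound_id])
    return retained
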