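"""Composite Z-score ranking: the synthesis-selection rubric.

Each of the three filter metrics — docking score D, shape similarity S and
QSAR-predicted potency Q — is normalized to the top-performing compound, and
candidates are ranked by

    Z_sum = D_i + S_i + Q_i          Z_avg = Z_sum / 3

The primary normalization is ratio-to-best ("normalized to the top
performing compound"); a min–max alternative is available behind the
``scheme`` switch because published normalized docking columns are not
exactly reproduced by either simple scheme.  Emitted tables round half-up
to two decimals while full precision is kept internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("hopscreen")

__all__ = ["ZScoreRecord", "normalize_metric", "composite_zscore", "select_candidates", "round2"]


@dataclass(frozen=True)
class ZScoreRecord:
    compound_id: str
    dock_norm: float
    shape_norm: float
    qsar_norm: float
    z_sum: float
    z_avg: float
    rank: int


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, matching table presentation."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_metric(
    values: Mapping[str, float],
    orientation: str = "higher_better",
    scheme: str = "ratio",
) -> dict[str, float]:
    """Normalize raw scores so the best compound maps to 1.0.

    ratio scheme: ``v / best`` for higher-is-better metrics; for
    lower-is-better metrics ``v / best`` when scores are negative (e.g.
    docking energies, best = most negative) and ``best / v`` when positive
    (e.g. predicted IC50).  minmax scheme: affine map of the range onto
    [0, 1] with the best value at 1.  All-equal inputs map to 1.0.
    """
    if not values:
        raise ValueError("normalize_metric: empty input")
    vals = dict(values)
    if any(not _finite(v) for v in vals.values()):
        raise ValueError("normalize_metric: non-finite value")
    if orientation not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    best = max(vals.values()) if orientation == "higher_better" else min(vals.values())
    worst = min(vals.values()) if orientation == "higher_better" else max(vals.values())
    if best == worst:
        return {k: 1.0 for k in vals}
    if scheme == "ratio":
        if orientation == "higher_better":
            return {k: v / best for k, v in vals.items()}
        if best < 0:
            return {k: v / best for k, v in vals.items()}
        return {k: best / v for k, v in vals.items()}
    if scheme == "minmax":
        return {k: (v - worst) / (best - worst) for k, v in vals.items()}
    raise ValueError(f"unknown scheme {scheme!r}")


def _finite(v: float) -> bool:
    return v == v and abs(v) != float("inf")


def composite_zscore(
    dock_norm: Mapping[str, float],
    shape_norm: Mapping[str, float],
    qsar_norm: Mapping[str, float],
) -> list[ZScoreRecord]:
    """Combine the three normalized metrics into ranked composite records.

    The three maps must share an identical id set; output is sorted by
    Z_avg descending, ties broken by Z_sum then id, and ranks are 1-based.
    """
    ids = set(dock_norm)
    if set(shape_norm) != ids or set(qsar_norm) != ids:
        missing = sorted((ids ^ set(shape_norm)) | (ids ^ set(qsar_norm)))
        raise ValueError(f"composite_zscore: id sets differ; mismatched ids: {missing}")
    rows = []
    for cid in ids:
        d, s, q = dock_norm[cid], shape_norm[cid], qsar_norm[cid]
        z_sum = d + s + q
        rows.append((cid, d, s, q, z_sum, z_sum / 3.0))
    rows.sort(key=lambda r: (-r[5], -r[4], r[0]))
    return [
        ZScoreRecord(cid, d, s, q, z_sum, z_avg, rank)
        for rank, (cid, d, s, q, z_sum, z_avg) in enumerate(rows, start=1)
    ]


def select_candidates(records: Sequence[ZScoreRecord], top_k: int) -> list[ZScoreRecord]:
    """First *top_k* records by the composite ordering."""
    if top_k <= 0:
        logger.warning("select_candidates: top_k <= 0, returning empty selection")
        return []
    if top_k > len(records):
        raise ValueError(f"top_k={top_k} exceeds {len(records)} records")
    ordered = sorted(records, key=lambda r: r.rank)
    return list(ordered[:top_k])


def to_table(records: Sequence[ZScoreRecord], path: str | Path | None = None) -> pd.DataFrame:
    """Emit the ranked table (two-decimal, half-up) as a DataFrame / CSV."""
    df = pd.DataFrame(
        {
            "rank": [r.rank for r in records],
            "name": [r.compound_id for r in records],
            "dock_norm": [round2(r.dock_norm) for r in records],
            "shape_norm": [round2(r.shape_norm) for r in records],
            "qsar_norm": [round2(r.qsar_norm) for r in records],
            "z_sum": [round2(r.z_sum) for r in records],
            "z_avg": [round2(r.z_avg) for r in records],
        }
    ).sort_values("rank")
    if path is not None:
        df.to_csv(path, index=False)
    return df
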