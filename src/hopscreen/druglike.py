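"""Druglikeness gate: Lipinski Rule-of-5 and Jorgensen Rule-of-3 violations.

Rule of 5 (oral druglikeness): MW <= 500, logP <= 5, H-bond donors <= 5,
H-bond acceptors <= 10; non-strict on the passing side.  Rule of 3
(absorption): logS > -5.7, Caco-2 permeability > 22 nm/s, predicted primary
metabolites < 7; strict as written.  Each report carries the violation
counts plus per-criterion values, and libraries are summarised as a
two-column (Ro5, Ro3) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chemio import Molecule, MoleculeProperties, compute_properties

logger = logging.getLogger("hopscreen")

__all__ = [
    "DruglikenessReport",
    "lipinski_violations",
    "jorgensen_violations",
    "druglikeness_report",
]

CriterionDetail = dict[str, tuple[float, bool]]  # name -> (measured value, passed)


@dataclass(frozen=True)
class DruglikenessReport:
    compound_id: str
    ro5_violations: int
    ro3_violations: int
    details: CriterionDetail
    flagged: bool = False


def lipinski_violations(props: MoleculeProperties) -> tuple[int, CriterionDetail]:
    details: CriterionDetail = {
        "mw<=500": (props.mw, props.mw <= 500.0),
        "logp<=5": (props.logp, props.logp <= 5.0),
        "hbd<=5": (float(props.hbd), props.hbd <= 5),
        "hba<=10": (float(props.hba), props.hba <= 10),
    }
    count = sum(1 for _, ok in details.values() if not ok)
    return count, details


def jorgensen_violations(props: MoleculeProperties) -> tuple[int, CriterionDetail]:
    details: CriterionDetail = {
        "logs>-5.7": (props.logs, props.logs > -5.7),
        "caco2>22nm/s": (props.caco2_perm, props.caco2_perm > 22.0),
        "metabolites<7": (float(props.n_primary_metabolites), props.n_primary_metabolites < 7),
    }
    count = sum(1 for _, ok in details.values() if not ok)
    return count, details


def druglikeness_report(mols: Sequence[Molecule]) -> list[DruglikenessReport]:
    """One report per molecule; property failures flag the report, never drop it."""
    reports: list[DruglikenessReport] = []
    for m in mols:
        try:
            props = compute_properties(m)
        except Exception:  # pragma: no cover - estimators are total on valid input
            logger.warning("property computation failed for %s", m.id)
            reports.append(DruglikenessReport(m.id, 0, 0, {}, flagged=True))
            continue
        n5, d5 = lipinski_violations(props)
        n3, d3 = jorgensen_violations(props)
        reports.append(DruglikenessReport(m.id, n5, n3, {**d5, **d3}))
    return reports


def to_table(reports: Sequence[DruglikenessReport], path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in reports],
            "rule_of_5": [r.ro5_violations for r in reports],
            "rule_of_3": [r.ro3_violations for r in reports],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def details_table(reports: Sequence[DruglikenessReport], path: str | Path | None = None) -> pd.DataFrame:
    rows = []
    for r in reports:
        for crit, (value, passed) in r.details.items():
            rows.append({"compound_id": r.compound_id, "criterion": crit, "value": value, "passed": passed})
    df = pd.DataFrame(rows, columns=["compound_id", "criterion", "value", "passed"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
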