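"""Config-driven orchestration of the full reductive filter.

Stage order is fixed: hybrid enumeration → reactive-alert screen → geometry
cleanup → shape filter → docking-score retention (controls added back) →
3D-QSAR prediction → composite Z-score ranking → druglikeness report.
Every stage writes a manifest (ids in, ids out, reason codes) and the run
emits its fully resolved configuration, so a run is replayable byte-for-byte
from (config, seed, inputs).

Docking scores are external inputs read from CSV; for self-contained fixture
runs the config may instead ask for synthetic scores drawn uniformly over a
stated range (tagged as synthetic in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemio, corehop, dockadapter, druglike, qsar, shapefilter, zranker
from .chemio import Molecule

logger = logging.getLogger("hopscreen")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "emit_report"]


@dataclass
class PipelineConfig:
    """Fully explicit run parameters; unknown keys are rejected at load."""

    parents_smiles: str = "parents.smi"
    cores_smiles: str = "cores.smi"
    training_smiles: str = "training.smi"
    activity_csv: str = "activities.csv"
    dock_scores_csv: str | None = None  # None -> synthetic scores over dock_range
    dock_range: tuple[float, float] = (-12.55, -7.0)
    seed: int = 7
    max_products: int = 2000
    pool_edges: bool = True
    n_conformers: int = 10
    shape_keep_threshold: float = 0.5
    dock_fraction: float = 0.5
    qsar_k_features: tuple[int, int] = (4, 6)
    qsar_max_hypotheses: int = 200
    qsar_tolerance: float = 2.0
    top_k: int = 10
    normalization_scheme: str = "ratio"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dock_range", "qsar_k_features"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["dock_range"] = list(data["dock_range"])
        data["qsar_k_features"] = list(data["qsar_k_features"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class StageManifest:
    stage: str
    n_in: int
    n_out: int
    reasons: dict[str, str] = field(default_factory=dict)  # id -> reason for drop/add


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifests: list[StageManifest]
    report: pd.DataFrame  # ranked Z-score table joined with druglikeness
    selected_ids: list[str]


def _halt_if_empty(stage: str, items) -> None:
    if not items:
        raise RuntimeError(f"pipeline halted: stage {stage!r} left zero survivors")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full funnel and write manifests, tables and the resolved
    config under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifests: list[StageManifest] = []

    parents = chemio.parse_molecules(config.parents_smiles, "smiles")
    cores = chemio.parse_molecules(config.cores_smiles, "smiles")
    _halt_if_empty("load-parents", parents)
    _halt_if_empty("load-cores", cores)

    # 1. core separation + hybrid enumeration
    fragment_sets = [corehop.separate_core(p) for p in parents]
    candidates = corehop.enumerate_hybrids(
        fragment_sets, cores, config.max_products, pool_edges=config.pool_edges
    )
    manifests.append(StageManifest("enumerate", len(parents), len(candidates)))
    _halt_if_empty("enumerate", candidates)

    # 2. reactive-alert screen
    passed, rejected = corehop.filter_reactive(candidates)
    manifests.append(
        StageManifest("reactive_filter", len(candidates), len(passed), {c.id: r for c, r in rejected})
    )
    _halt_if_empty("reactive_filter", passed)

    # 3. geometry cleanup + conformer ensembles for the shape screen
    library: list[Molecule] = []
    dropped: dict[str, str] = {}
    for cand in passed:
        try:
            ens = shapefilter.generate_conformer_ensemble(
                cand.molecule, config.n_conformers, seed=config.seed
            )
            library.append(ens)
        except ValueError:
            dropped[cand.id] = "embedding failure"
    manifests.append(StageManifest("geometry", len(passed), len(library), dropped))
    _halt_if_empty("geometry", library)

    # 4. shape filter against the parent inhibitors
    references = [
        shapefilter.generate_conformer_ensemble(p, config.n_conformers, seed=config.seed)
        for p in parents
    ]
    shape_scores, top_ref = shapefilter.shape_screen(
        library, references, config.n_conformers, config.shape_keep_threshold, seed=config.seed
    )
    shape_by_id = {s.candidate_id: s.similarity for s in shape_scores}
    survivors = [m for m in library if m.id in shape_by_id]
    manifests.append(
        StageManifest(
            "shape",
            len(library),
            len(survivors),
            {m.id: "below shape threshold" for m in library if m.id not in shape_by_id},
        )
    )
    logger.info("shape filter: best-covering reference %s", top_ref)
    _halt_if_empty("shape", survivors)

    # 5. docking-score retention; parents ride along as controls
    controls = [p.id for p in parents]
    if config.dock_scores_csv is not None:
        dock_scores = dockadapter.read_dock_scores(config.dock_scores_csv)
    else:
        rng = np.random.default_rng(config.seed)
        lo, hi = config.dock_range
        dock_scores = [
            dockadapter.DockScore(m.id, float(rng.uniform(lo, hi)), "synthetic")
            for m in survivors
        ] + [dockadapter.DockScore(c, float(rng.uniform(lo, hi)), "control") for c in controls]
    known_ids = {m.id for m in survivors} | set(controls)
    dock_scores = [s for s in dock_scores if s.compound_id in known_ids]
    retained = dockadapter.retain_top_fraction(dock_scores, config.dock_fraction, controls)
    retained_ids = {s.compound_id for s in retained}
    dockadapter.write_dock_scores(dock_scores, out / "dock_scores.csv", retained_ids)
    manifests.append(
        StageManifest(
            "dock_retention",
            len(dock_scores),
            len(retained),
            {cid: "control added" for cid in controls if cid in retained_ids},
        )
    )
    pool = [m for m in survivors if m.id in retained_ids]
    _halt_if_empty("dock_retention", pool)

    # 6. QSAR: train on the known-compound set, predict the pool
    training = _load_training(config)
    hyps = qsar.enumerate_hypotheses(
        training,
        k_features=config.qsar_k_features,
        max_hypotheses=config.qsar_max_hypotheses,
        tolerance=config.qsar_tolerance,
    )
    _halt_if_empty("qsar_hypotheses", hyps)
    ranked_hyps = qsar.rank_hypotheses(hyps, training)
    model = None
    for _, hyp in ranked_hyps:
        try:
            model = qsar.fit_qsar(training, hyp)
            break
        except ValueError:
            continue
    if model is None:
        raise RuntimeError("pipeline halted: stage 'qsar_fit' found no fittable hypothesis")
    predictions = {m.id: qsar.predict_activity(model, m) for m in pool}
    manifests.append(StageManifest("qsar_predict", len(pool), len(predictions)))

    # 7. composite Z-score
    dock_map = {s.compound_id: s.score for s in retained if s.compound_id in predictions}
    shape_map = {cid: shape_by_id[cid] for cid in predictions}
    qsar_map = {cid: rec.predicted_ic50 for cid, rec in predictions.items()}
    scheme = config.normalization_scheme
    d_norm = zranker.normalize_metric(dock_map, "lower_better", scheme)
    s_norm = zranker.normalize_metric(shape_map, "higher_better", scheme)
    q_norm = zranker.normalize_metric(qsar_map, "lower_better", scheme)
    records = zranker.composite_zscore(d_norm, s_norm, q_norm)
    top_k = min(config.top_k, len(records))
    selected = zranker.select_candidates(records, top_k)
    manifests.append(StageManifest("zscore_select", len(records), len(selected)))

    # 8. druglikeness on the selection
    by_id = {m.id: m for m in pool}
    reports = druglike.druglikeness_report([by_id[r.compound_id] for r in selected])
    druglike.to_table(reports, out / "druglikeness.csv")
    druglike.details_table(reports, out / "druglikeness_details.csv")
    manifests.append(StageManifest("druglike", len(selected), len(reports)))

    ztable = zranker.to_table(records, out / "zscore_full.csv")
    dl = {r.compound_id: r for r in reports}
    report = ztable[ztable["name"].isin([r.compound_id for r in selected])].copy()
    report["rule_of_5"] = [dl[n].ro5_violations for n in report["name"]]
    report["rule_of_3"] = [dl[n].ro3_violations for n in report["name"]]
    report.to_csv(out / "final_report.csv", index=False)

    result = PipelineResult(config, manifests, report, [r.compound_id for r in selected])
    emit_report(result, out)
    return result


def _load_training(config: PipelineConfig) -> list[tuple[Molecule, qsar.ActivityRecord]]:
    mols = {m.id: m for m in chemio.parse_molecules(config.training_smiles, "smiles")}
    acts = pd.read_csv(config.activity_csv, dtype={"compound_id": str})
    training = []
    for _, row in acts.iterrows():
        cid = str(row["compound_id"])
        if cid not in mols:
            logger.warning("training activity for unknown compound %s", cid)
            continue
        censored = bool(row["censored"]) if "censored" in acts.columns else False
        rec = qsar.ActivityRecord.from_ic50(cid, float(row["ic50_nM"]), censored=censored)
        mol = mols[cid]
        if mol.n_conformers == 0:
            mol = shapefilter.generate_conformer_ensemble(mol, config.n_conformers, seed=config.seed)
        training.append((mol, rec))
    return training


def emit_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write stage manifests and a human-readable funnel summary."""
    out = Path(out_dir)
    manifest_rows = [
        {"stage": m.stage, "n_in": m.n_in, "n_out": m.n_out, "n_reasons": len(m.reasons)}
        for m in result.manifests
    ]
    pd.DataFrame(manifest_rows).to_csv(out / "stage_manifests.csv", index=False)
    with open(out / "stage_reasons.json", "w") as fh:
        json.dump({m.stage: m.reasons for m in result.manifests}, fh, indent=2, sort_keys=True)
    lines = ["screening funnel:"]
    for m in result.manifests:
        lines.append(f"  {m.stage:>16}: {m.n_in:5d} -> {m.n_out:5d}")
    lines.append(f"selected for synthesis review: {len(result.selected_ids)}")
    lines.append("top candidates: " + ", ".join(result.selected_ids[:5]))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
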