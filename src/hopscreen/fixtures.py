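"""Deterministic synthetic-input generators and packaged reference tables.

Everything the test surface needs is generated here from a seeded
:class:`FixtureSpec`:

* fragment fixtures — decomposable parent inhibitors (heteroaryl scaffolds
  with small peripheral substituents, emulating the SCD1-inhibitor
  chemotypes the screen starts from) plus a replacement-core library;
* QSAR fixtures — a training set with a *planted linear* structure–activity
  relationship over the real grid descriptors, for parameter-recovery tests;
* docking fixtures — synthetic scores uniform over the working range of a
  docking run (default -12.55 to -7 kcal/mol).

The packaged reference tables (published activity ranking, composite
Z-score table and druglikeness violation counts from the SCD1 screening
campaign) ship as CSV and are checksum-guarded against drift.  The
replacement-core library here is explicitly a stand-in: the original
campaign's core pool was never published.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import Molecule, from_smiles
from .corehop import separate_core
from .dockadapter import DockScore
from .qsar import (
    ActivityRecord,
    GridSpec,
    PharmacophoreHypothesis,
    compute_descriptors,
    perceive_features,
)
from .shapefilter import generate_conformer_ensemble

__all__ = [
    "FixtureSpec",
    "make_fragment_fixture",
    "make_qsar_fixture",
    "make_dock_fixture",
    "load_reference_tables",
    "QsarFixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study; identical specs reproduce
    byte-identical fixtures."""

    seed: int = 7
    n_parents: int = 3
    n_cores: int = 30
    n_library: int = 60
    n_qsar: int = 32
    qsar_noise_sigma: float = 0.0  # log units
    n_dock: int = 286
    dock_range: tuple[float, float] = (-12.55, -7.0)
    n_conformers: int = 10


# --------------------------------------------------------------------------
# fragment fixtures
# --------------------------------------------------------------------------

# three-attachment-point ring scaffolds used to assemble parents
_PARENT_SCAFFOLDS = [
    "[1*]c1nnc(-c2ccc(N3CCC(Oc4ccc([3*])cc4[2*])CC3)nn2)s1",
    "[1*]c1ccc(-c2nc3ccc([2*])cc3s2)cc1[3*]",
    "[1*]c1ccc(N2CCN(C(=O)c3ccc([2*])cc3[3*])CC2)nn1",
    "[1*]c1ccc(Oc2ncnc(N3CCC([2*])CC3)c2[3*])cc1",
    "[1*]c1csc(-c2ccc(N3CCN([2*])CC3)c([3*])n2)n1",
]

# peripheral substituents; carbon-linked, one open attachment point each,
# no reactive alerts
_EDGE_POOL = [
    "[1*]C",
    "[1*]CC",
    "[1*]CCC",
    "[1*]COC",
    "[1*]C(F)(F)F",
    "[1*]CCO",
    "[1*]C(C)C",
    "[1*]CC(C)C",
    "[1*]CCOC",
    "[1*]CC(F)(F)F",
    "[1*]CCCO",
    "[1*]C(C)CC",
]

# replacement cores: ring systems with 1-3 attachment points
_CORE_TEMPLATES = [
    "[1*]c1ccc([2*])cc1",
    "[1*]c1ccc([2*])nc1",
    "[1*]c1ccc([2*])nn1",
    "[1*]c1nnc([2*])s1",
    "[1*]c1csc([2*])n1",
    "[1*]c1cnc([2*])cn1",
    "[1*]c1ccc2nc([2*])sc2c1",
    "[1*]c1ccc2nc([2*])oc2c1",
    "[1*]c1oc([2*])cc1",
    "[1*]c1cc([2*])no1",
    "[1*]C1CCN([2*])CC1",
    "[1*]C1CCC([2*])CC1",
    "[1*]c1ccc(-c2ccc([2*])cc2)cc1",
    "[1*]c1ccc(-c2ccc([2*])nn2)cc1",
    "[1*]c1ccc(N2CCC([2*])CC2)nn1",
    "[1*]c1ccc(N2CCN([2*])CC2)cn1",
    "[1*]c1ccc(OC2CCN([2*])CC2)cc1",
    "[1*]c1nc2ccc([2*])cc2o1",
    "[1*]c1cnn([2*])c1",
    "[1*]c1ccc([2*])s1",
    "[1*]c1ccc([2*])o1",
    "[1*]c1nnc([2*])o1",
    "[1*]C1CCN(c2ccc([2*])nn2)CC1",
    "[1*]c1ccc(CN2CCC([2*])CC2)cc1",
    "[1*]c1cc([2*])ncn1",
    "[1*]c1ccccc1",
    "[1*]c1ccncc1",
    "[1*]C1CCNCC1",
    "[1*]c1cc([2*])cc([3*])c1",
    "[1*]c1nc([2*])cc([3*])n1",
]


def make_fragment_fixture(
    spec: FixtureSpec, outdir: str | Path | None = None
) -> tuple[list[Molecule], list[Molecule]]:
    """Generate decomposable parent molecules and a replacement-core library.

    Every parent carries a ring scaffold with exactly three peripheral
    substituents, so ``separate_core`` succeeds by construction (validated
    here).  When *outdir* is given, ``parents.smi`` and ``cores.smi`` are
    written with the seed recorded in a header comment.
    """
    rng = np.random.default_rng(spec.seed)
    parents: list[Molecule] = []
    # distinct substituents across parents where the pool allows, so the
    # pooled edge set is as diverse as the real periphery fragments
    n_edges = 3 * spec.n_parents
    if n_edges <= len(_EDGE_POOL):
        edge_draw = [_EDGE_POOL[j] for j in rng.permutation(len(_EDGE_POOL))[:n_edges]]
    else:
        edge_draw = [_EDGE_POOL[int(j)] for j in rng.integers(len(_EDGE_POOL), size=n_edges)]
    for i in range(spec.n_parents):
        scaffold = _PARENT_SCAFFOLDS[int(rng.integers(len(_PARENT_SCAFFOLDS)))]
        combined = Chem.MolFromSmiles(scaffold)
        for label in (1, 2, 3):
            edge = edge_draw[3 * i + (label - 1)]
            combined = Chem.CombineMols(
                combined, Chem.MolFromSmiles(edge.replace("[1*]", f"[{label}*]"))
            )
        params = Chem.MolzipParams()
        params.label = Chem.MolzipLabel.Isotope
        mol = Chem.molzip(combined, params)
        Chem.SanitizeMol(mol)
        parent = Molecule(id=f"parent{i + 1}", mol=mol, source="generated")
        separate_core(parent)  # self-validation: decomposable by construction
        parents.append(parent)
    core_idx = rng.permutation(len(_CORE_TEMPLATES))[: spec.n_cores]
    cores = [
        from_smiles(_CORE_TEMPLATES[j], f"core{rank + 1}", source="generated")
        for rank, j in enumerate(sorted(core_idx))
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_smi_with_header(parents, outdir / "parents.smi", spec.seed)
        _write_smi_with_header(cores, outdir / "cores.smi", spec.seed)
    return parents, cores


def _write_smi_with_header(mols: list[Molecule], path: Path, seed: int) -> None:
    body = "\n".join(f"{m.smiles}\t{m.id}" for m in mols)
    path.write_text(f"# hopscreen fixture, seed={seed}\n{body}\n")


# --------------------------------------------------------------------------
# QSAR fixtures
# --------------------------------------------------------------------------

# rigid anilide scaffold shared by every training compound; the alkyl tail
# varies, so descriptor variation is confined to a small structural family
_QSAR_SCAFFOLD = "NC(=O)c1ccc({tail})cc1"
_QSAR_TAILS = ["CCC", "CCCC", "CCCCC", "CCCCCC", "OCCC", "OCCCC"]


@dataclass
class QsarFixture:
    """Training set with a planted linear structure-activity relationship."""

    training: list[tuple[Molecule, ActivityRecord]]
    hypothesis: PharmacophoreHypothesis
    grid: GridSpec
    descriptors: np.ndarray  # row per training compound
    planted_weights: np.ndarray  # full-length weight vector (two nonzero columns)
    planted_intercept: float
    planted_columns: tuple[int, int]
    noise_sigma: float

    def planted_pic50(self, x: np.ndarray) -> float:
        """The noiseless planted activity for a descriptor vector."""
        return float(x @ self.planted_weights + self.planted_intercept)


def _qsar_family(spec: FixtureSpec) -> list[Molecule]:
    """The six distinct structures of the training family, with seeded
    conformer ensembles (identical SMILES always embeds identically)."""
    mols = []
    for i, tail in enumerate(_QSAR_TAILS):
        m = from_smiles(_QSAR_SCAFFOLD.format(tail=tail), f"fam{i + 1}", source="generated")
        mols.append(generate_conformer_ensemble(m, spec.n_conformers, seed=spec.seed))
    return mols


def make_qsar_fixture(spec: FixtureSpec) -> QsarFixture:
    """Build a training set whose pIC50 is a planted linear function of two
    grid-descriptor columns, plus optional Gaussian noise (log units).

    The *n_qsar* compounds sample a six-member structural family with
    repeats; activities are scaled to span >= 3.8 log units (IC50 from
    ~10,000 nM down to low nM, mirroring a realistic training spread) and
    the most inactive compound is flagged as a censored ">" bound.
    """
    rng = np.random.default_rng(spec.seed)
    family = _qsar_family(spec)
    # hypothesis from the first family member's shared scaffold features
    ref_feats = [f for f in perceive_features(family[0]) if f.kind in ("A", "D", "R")]
    if len(ref_feats) < 3:  # pragma: no cover - fixed scaffold has A, D, R
        raise AssertionError("fixture scaffold lost its anchor features")
    kinds = tuple(f.kind for f in ref_feats)
    sites = tuple(f.position for f in ref_feats)
    hyp = PharmacophoreHypothesis(label="".join(sorted(kinds)) + ".fixture", kinds=kinds, sites=sites, tolerance=2.0)
    grid = GridSpec.around(hyp.site_array, margin=4.0, spacing=2.0)
    fam_x = np.vstack([compute_descriptors(m, hyp, grid)[0] for m in family])
    # two informative, mutually decorrelated descriptor columns carry the
    # planted signal so the activities take several distinct levels
    variances = fam_x.var(axis=0)
    order = np.argsort(variances)[::-1]
    j1 = int(order[0])
    j2 = None
    for j in order[1:]:
        if variances[j] <= 0:
            break
        c = np.corrcoef(fam_x[:, j1], fam_x[:, j])[0, 1]
        if abs(c) < 0.95:
            j2 = int(j)
            break
    if j2 is None:  # pragma: no cover - family is structurally diverse
        j2 = int(order[1])
    raw = fam_x[:, j1] - 0.5 * fam_x[:, j2]
    span = raw.max() - raw.min()
    scale = 3.8 / span
    w = np.zeros(fam_x.shape[1])
    w[j1], w[j2] = scale, -0.5 * scale
    b = 5.0 - scale * raw.min() + scale * raw.min() * 0  # pIC50 floor at 5 (10,000 nM)
    b = 5.0 - raw.min() * scale

    members = rng.integers(len(family), size=spec.n_qsar)
    # guarantee every family member appears so the planted span is realised
    members[: len(family)] = np.arange(len(family))
    training: list[tuple[Molecule, ActivityRecord]] = []
    xs = []
    pic50s = fam_x[members] @ w + b
    if spec.qsar_noise_sigma > 0:
        pic50s = pic50s + rng.normal(0.0, spec.qsar_noise_sigma, size=len(members))
    worst = int(np.argmin(pic50s))
    for i, (fam_i, pic50) in enumerate(zip(members, pic50s)):
        mol = family[fam_i].copy()
        mol.id = f"trn{i + 1:02d}"
        rec = ActivityRecord.from_ic50(
            mol.id, 10.0 ** (9.0 - pic50), source="measured", censored=(i == worst)
        )
        training.append((mol, rec))
        xs.append(fam_x[fam_i])
    return QsarFixture(
        training=training,
        hypothesis=hyp,
        grid=grid,
        descriptors=np.vstack(xs),
        planted_weights=w,
        planted_intercept=b,
        planted_columns=(j1, j2),
        noise_sigma=spec.qsar_noise_sigma,
    )


# potency levels (pIC50) assigned by family structure in the winner fixture:
# the first three tails form a tight potent tier, the rest a weak tier
_WINNER_PIC50 = [8.8, 8.75, 8.7, 5.0, 5.15, 5.3]


def make_winner_training(
    spec: FixtureSpec,
) -> tuple[list[tuple[Molecule, ActivityRecord]], list[str]]:
    """Training set for the planted-winner pipeline experiment.

    Activities are assigned by structure: the first three family members
    form a tight, clearly potent tier (pIC50 8.7-8.8), the other three a
    weak tier, so an in-sample prediction for a potent-tier copy beats any
    other candidate's clamped prediction by a controlled margin.  Returns
    the (molecule, activity) pairs and the potent-tier SMILES.
    """
    rng = np.random.default_rng(spec.seed)
    family = _qsar_family(spec)
    members = rng.integers(len(family), size=spec.n_qsar)
    members[: len(family)] = np.arange(len(family))
    training: list[tuple[Molecule, ActivityRecord]] = []
    for i, fam_i in enumerate(members):
        mol = family[fam_i].copy()
        mol.id = f"trn{i + 1:02d}"
        pic50 = _WINNER_PIC50[fam_i]
        training.append(
            (
                mol,
                ActivityRecord.from_ic50(
                    mol.id, 10.0 ** (9.0 - pic50), source="measured", censored=(pic50 == min(_WINNER_PIC50))
                ),
            )
        )
    planted = [family[i].smiles for i in range(3)]
    return training, planted


# --------------------------------------------------------------------------
# planted-pharmacophore fixture
# --------------------------------------------------------------------------

# five actives sharing a biphenyl-anilide scaffold that carries the planted
# 6-feature arrangement (amide A+D, methoxy A, alkyl H, two rings: AADHRR);
# the two most active compounds carry an extra methoxy so that competing
# (non-shared) arrangements exist and must be out-ranked
_PHARM_ACTIVES = [
    "NC(=O)c1ccc(-c2ccc(OC)cc2OC)cc1CCC",
    "NC(=O)c1ccc(-c2ccc(OC)cc2OC)cc1CCCC",
    "NC(=O)c1ccc(-c2ccccc2OC)cc1CCC",
    "NC(=O)c1cc(F)cc(-c2ccccc2OC)c1CCC",
    "NC(=O)c1ccc(-c2ccc(C)cc2OC)cc1CCC",
]


def make_pharmacophore_fixture(spec: FixtureSpec) -> tuple[list[tuple[Molecule, ActivityRecord]], PharmacophoreHypothesis]:
    """Five actives built around a planted 6-feature arrangement.

    Returns the (molecule, activity) pairs plus the planted hypothesis: the
    6 shared scaffold features of the most active compound.
    """
    actives = []
    for i, smi in enumerate(_PHARM_ACTIVES):
        m = from_smiles(smi, f"act{i + 1}", source="generated")
        m = generate_conformer_ensemble(m, spec.n_conformers, seed=spec.seed)
        rec = ActivityRecord.from_ic50(m.id, 10.0 * (i + 1), source="measured")
        actives.append((m, rec))
    # the planted arrangement is the full feature set of the bare scaffold
    # (third active), which every compound shares
    ref = actives[2][0]
    shared = perceive_features(ref)
    if len(shared) != 6:  # pragma: no cover - fixed scaffold
        raise AssertionError(f"planted scaffold yields {len(shared)} anchor features, expected 6")
    kinds = tuple(f.kind for f in shared)
    hyp = PharmacophoreHypothesis(
        label="".join(sorted(kinds)) + ".planted",
        kinds=kinds,
        sites=tuple(f.position for f in shared),
        tolerance=2.0,
    )
    return actives, hyp


# --------------------------------------------------------------------------
# docking fixtures
# --------------------------------------------------------------------------

def make_dock_fixture(
    spec: FixtureSpec,
    ids: list[str] | None = None,
    controls: list[str] | None = None,
    outfile: str | Path | None = None,
) -> list[DockScore]:
    """Synthetic docking scores uniform over ``spec.dock_range``.

    Controls are tagged ``source='control'``; everything else is tagged
    ``source='synthetic'``.  The extreme scores are pinned to the range
    bounds so the generated set round-trips the generator's bounds exactly.
    """
    lo, hi = spec.dock_range
    if not lo < hi < 0:
        raise ValueError("dock_range must satisfy min < max < 0")
    controls = list(controls or [])
    if ids is None:
        ids = [f"cand{i + 1:04d}" for i in range(spec.n_dock - len(controls))]
    rng = np.random.default_rng(spec.seed)
    scores = rng.uniform(lo, hi, size=len(ids))
    if len(ids) >= 2:
        scores[0], scores[-1] = lo, hi
    records = [DockScore(cid, float(s), "synthetic") for cid, s in zip(ids, scores)]
    control_scores = rng.uniform(lo, hi, size=len(controls))
    records += [DockScore(cid, float(s), "control") for cid, s in zip(controls, control_scores)]
    if outfile is not None:
        pd.DataFrame(
            [{"compound_id": r.compound_id, "score": r.score, "source": r.source} for r in records]
        ).to_csv(outfile, index=False)
    return records


# --------------------------------------------------------------------------
# packaged reference tables
# --------------------------------------------------------------------------

_TABLE_CHECKSUMS = {
    "activity_ranking.csv": "250f89603c2853e5bcacc8e8c17ea36e3a15e2716040c24fabd588188897be52",
    "zscore_table.csv": "7878fc8399a60d119bdcbf10720eebf3f7fe3da81f898d4375946226447320d0",
    "druglikeness_table.csv": "2105f87a3fe2b47543ff80ca0ba317892239d5bd995f7390348002202ac6ca73",
}


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged published tables from the SCD1 screening campaign.

    Returns ``activity_ranking`` (59 rows: predicted-activity ranking with
    the <500 nM gate), ``zscore`` (50 rows: normalized sub-metrics and
    composite Z-scores) and ``druglikeness`` (44 rows: Ro5/Ro3 violation
    counts).  A checksum mismatch is fatal — it means the fixture drifted.
    """
    out: dict[str, pd.DataFrame] = {}
    names = {
        "activity_ranking": "activity_ranking.csv",
        "zscore": "zscore_table.csv",
        "druglikeness": "druglikeness_table.csv",
    }
    for key, fname in names.items():
        raw = resources.files("hopscreen.data").joinpath(fname).read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE_CHECKSUMS[fname]:
            raise RuntimeError(f"reference table {fname} failed its checksum (fixture drift)")
        from io import BytesIO

        out[key] = pd.read_csv(BytesIO(raw))
    return out
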