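"""Pharmacophore-hypothesis 3D-QSAR: the third reductive filter.

The model follows the classical ligand-based recipe:

1. *Feature perception* — each conformer is reduced to typed pharmacophore
   points: A (acceptor), D (donor), H (hydrophobe: aliphatic-carbon cluster
   of >= 3 atoms), N / P (ionizable at pH 7.4 by rule), R (one feature per
   aromatic ring, at its centroid).
2. *Hypothesis enumeration* — k-feature arrangements (kinds + inter-feature
   distances) taken from the most active compound and required to be common,
   within a distance tolerance, to every compound in the top activity tier.
   Labels are the sorted kind string plus a running index (e.g. AAHR.12).
3. *Alignment* — candidate conformers are matched to a hypothesis by a
   kind-respecting feature assignment and superposed with the Kabsch
   algorithm; the fit score is the site RMSD, minimized over conformers and
   assignments.
4. *Regression* — aligned molecules are rasterized into per-kind Gaussian
   occupancies on a fixed 3D grid around the hypothesis and pIC50 is fit by
   partial least squares, with the component count chosen by leave-one-out
   cross-validation.

Activities are handled as IC50 in nM with pIC50 = 9 - log10(IC50/nM);
censored ">" bounds enter the regression at the bound value and are flagged.
Molecules that fail to match the hypothesis receive a flagged worst-tier
prediction (10x the worst training IC50) so downstream normalization is
total.  The experimental-feedback loop refits the same hypothesis and grid
on the augmented training set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from sklearn.cross_decomposition import PLSRegression

from .chemio import Molecule

logger = logging.getLogger("hopscreen")

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreHypothesis",
    "ActivityRecord",
    "QsarModel",
    "AlignmentResult",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "perceive_features",
    "enumerate_hypotheses",
    "align_to_hypothesis",
    "hypothesis_training_fit",
    "rank_hypotheses",
    "fit_qsar",
    "predict_activity",
    "update_with_experimental",
    "classify_under_threshold",
]

FEATURE_KINDS = "ADHNPR"
UNMATCHED_SENTINEL = float("inf")


# --------------------------------------------------------------------------
# activity records and unit conversions
# --------------------------------------------------------------------------

def pic50_from_ic50(ic50_nm: float) -> float:
    """pIC50 from an IC50 in nM: pIC50 = 9 - log10(IC50)."""
    if ic50_nm <= 0:
        raise ValueError("IC50 must be positive")
    return 9.0 - math.log10(ic50_nm)


def ic50_from_pic50(pic50: float) -> float:
    return 10.0 ** (9.0 - pic50)


@dataclass(frozen=True)
class ActivityRecord:
    """Measured or predicted potency for one compound."""

    compound_id: str
    ic50: float  # nM
    pic50: float
    source: str = "measured"  # measured | predicted
    censored: bool = False  # True when the IC50 was a ">" bound
    matched: bool = True  # False for worst-tier fallback predictions

    @classmethod
    def from_ic50(cls, compound_id: str, ic50_nm: float, source: str = "measured", censored: bool = False) -> "ActivityRecord":
        return cls(compound_id, float(ic50_nm), pic50_from_ic50(ic50_nm), source, censored)

    @classmethod
    def from_pic50(cls, compound_id: str, pic50: float, source: str = "predicted", matched: bool = True) -> "ActivityRecord":
        return cls(compound_id, ic50_from_pic50(pic50), float(pic50), source, False, matched)

    @property
    def predicted_ic50(self) -> float:
        """Predicted IC50 in nM (identical to ``ic50`` for predicted records)."""
        return self.ic50


# --------------------------------------------------------------------------
# feature perception
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str  # one of A D H N P R
    position: tuple[float, float, float]
    atoms: tuple[int, ...]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position)


_ACCEPTOR = Chem.MolFromSmarts(
    "[$([OX2;!$([OX2][Si])]),$([OX1]),$([NX2;!$([NX2]=[NX2+])]),$([nX2]),"
    "$([NX3;H0;!$([NX3][CX3]=[OX1]);!$([NX3][SX4]=[OX1]);!$([NX3]c)])]"
)
_DONOR = Chem.MolFromSmarts("[$([OX2H]),$([NX3;H1,H2,H3]),$([nX3H])]")
_NEG = [
    Chem.MolFromSmarts(s)
    for s in ("[CX3](=[OX1])[OX2H1,OX1-]", "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]", "[PX4](=[OX1])([OX2H1,OX1-])")
]
_POS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[NX3;H2,H1,H0;!$(N[a]);!$(N[C,S,P]=[O,S,N]);!$(N=*);$(N[CX4])]",
        "[NX3][CX3]=[NX2]",  # amidine / guanidine
        "[NX4+]",
    )
]


def perceive_features(molecule: Molecule, conf_id: int = 0) -> list[PharmacophoreFeature]:
    """Typed pharmacophore points for one conformer.

    Positions are atom (or group/ring centroid) coordinates in Å.  The
    feature dictionary is fixed: every all-aromatic ring yields exactly one
    R feature at its centroid; hydrophobes are connected clusters of >= 3
    aliphatic carbons with only C/H neighbours.
    """
    mol = molecule.mol
    if mol.GetNumConformers() <= conf_id:
        raise ValueError(f"molecule {molecule.id!r} has no conformer {conf_id}")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    feats: list[PharmacophoreFeature] = []

    def add(kind: str, atom_ids: Iterable[int]) -> None:
        ids = tuple(sorted(set(atom_ids)))
        centroid = pos[list(ids)].mean(axis=0)
        feats.append(PharmacophoreFeature(kind, tuple(float(v) for v in centroid), ids))

    for (idx,) in mol.GetSubstructMatches(_ACCEPTOR):
        add("A", [idx])
    for (idx,) in mol.GetSubstructMatches(_DONOR):
        add("D", [idx])
    for patt in _NEG:
        for match in mol.GetSubstructMatches(patt):
            add("N", match)
    for patt in _POS:
        for match in mol.GetSubstructMatches(patt):
            add("P", [match[0]])
    # hydrophobe clusters: aliphatic carbons whose neighbours are all C/H
    aliph = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6
        and not a.GetIsAromatic()
        and all(n.GetAtomicNum() in (1, 6) for n in a.GetNeighbors())
    }
    seen: set[int] = set()
    for start in sorted(aliph):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            for n in mol.GetAtomWithIdx(cur).GetNeighbors():
                if n.GetIdx() in aliph and n.GetIdx() not in comp:
                    stack.append(n.GetIdx())
        seen |= comp
        if len(comp) >= 3:
            add("H", comp)
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            add("R", ring)
    # deduplicate identical (kind, atoms) features from overlapping patterns
    uniq: dict[tuple[str, tuple[int, ...]], PharmacophoreFeature] = {}
    for f in feats:
        uniq.setdefault((f.kind, f.atoms), f)
    out = list(uniq.values())
    out.sort(key=lambda f: (f.kind, f.atoms))
    return out


# --------------------------------------------------------------------------
# hypotheses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PharmacophoreHypothesis:
    """A k-feature arrangement: kinds, 3D sites and a matching tolerance."""

    label: str
    kinds: tuple[str, ...]
    sites: tuple[tuple[float, float, float], ...]
    tolerance: float = 2.0  # Å

    @property
    def k(self) -> int:
        return len(self.kinds)

    @property
    def site_array(self) -> np.ndarray:
        return np.asarray(self.sites)

    @property
    def distance_matrix(self) -> np.ndarray:
        s = self.site_array
        return np.linalg.norm(s[:, None, :] - s[None, :, :], axis=-1)

    @property
    def kind_string(self) -> str:
        return "".join(sorted(self.kinds))


def _distance_assignment_exists(
    features: Sequence[PharmacophoreFeature],
    kinds: Sequence[str],
    dmat: np.ndarray,
    tol: float,
    max_nodes: int = 20000,
) -> bool:
    """Backtracking search for a kind-respecting, distance-compatible
    assignment of molecule features to hypothesis sites."""
    by_kind: dict[str, list[PharmacophoreFeature]] = {}
    for f in features:
        by_kind.setdefault(f.kind, []).append(f)
    k = len(kinds)
    chosen: list[PharmacophoreFeature] = []
    nodes = 0

    def backtrack(site: int) -> bool:
        nonlocal nodes
        if site == k:
            return True
        for cand in by_kind.get(kinds[site], []):
            nodes += 1
            if nodes > max_nodes:
                return False
            if any(cand is c for c in chosen):
                continue
            ok = True
            for prev_site, prev in enumerate(chosen):
                d = float(np.linalg.norm(cand.xyz - prev.xyz))
                if abs(d - dmat[site, prev_site]) > tol:
                    ok = False
                    break
            if ok:
                chosen.append(cand)
                if backtrack(site + 1):
                    return True
                chosen.pop()
        return False

    return backtrack(0)


def enumerate_hypotheses(
    actives: Sequence[tuple[Molecule, ActivityRecord]],
    k_features: tuple[int, int] = (4, 7),
    max_hypotheses: int = 20000,
    tolerance: float = 2.0,
) -> list[PharmacophoreHypothesis]:
    """Enumerate k-feature arrangements common to the top activity tier.

    The tier is the top quartile by pIC50 (always >= 2 compounds); candidate
    arrangements are k-subsets of the most active compound's features, kept
    when every other tier compound admits a kind-respecting assignment whose
    pairwise distances agree within *tolerance* on at least one conformer.
    Enumeration order (k ascending, then feature-index order) and labels
    (sorted kind string + running index) are deterministic.
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 actives")
    ranked = sorted(actives, key=lambda p: (-p[1].pic50, p[1].compound_id))
    n_tier = max(2, math.ceil(len(ranked) / 4))
    tier = ranked[:n_tier]
    ref_mol = tier[0][0]
    ref_feats = perceive_features(ref_mol)
    other_feats = [
        [perceive_features(m, c) for c in range(m.n_conformers)] for m, _ in tier[1:]
    ]
    out: list[PharmacophoreHypothesis] = []
    counter = 0
    k_lo, k_hi = k_features
    for k in range(k_lo, k_hi + 1):
        if k > len(ref_feats):
            break
        for subset in itertools.combinations(range(len(ref_feats)), k):
            feats = [ref_feats[i] for i in subset]
            kinds = tuple(f.kind for f in feats)
            sites = tuple(f.position for f in feats)
            hyp = PharmacophoreHypothesis("", kinds, sites, tolerance)
            dmat = hyp.distance_matrix
            if all(
                any(_distance_assignment_exists(fl, kinds, dmat, tolerance) for fl in conf_feats)
                for conf_feats in other_feats
            ):
                counter += 1
                out.append(replace(hyp, label=f"{hyp.kind_string}.{counter}"))
                if len(out) >= max_hypotheses:
                    return out
    if not out:
        logger.warning("enumerate_hypotheses: no common feature arrangement found")
    return out


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    fit_score: float  # RMSD (Å) of matched feature centroids; inf if unmatched
    matched: bool
    aligned_conformer: int
    rotation: np.ndarray | None = None  # maps conformer coords onto hypothesis frame
    translation: np.ndarray | None = None


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of src onto dst; returns (rmsd, R, t)
    with dst ~= src @ R.T + t."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = dc - rot @ sc
    moved = src @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=-1))))
    return rmsd, rot, t


def _assignments(
    features: Sequence[PharmacophoreFeature],
    kinds: Sequence[str],
    dmat: np.ndarray,
    tol: float,
    max_nodes: int = 20000,
):
    """Yield kind-respecting, distance-compatible feature assignments."""
    by_kind: dict[str, list[PharmacophoreFeature]] = {}
    for f in features:
        by_kind.setdefault(f.kind, []).append(f)
    k = len(kinds)
    chosen: list[PharmacophoreFeature] = []
    nodes = 0

    def backtrack(site: int):
        nonlocal nodes
        if site == k:
            yield list(chosen)
            return
        for cand in by_kind.get(kinds[site], []):
            nodes += 1
            if nodes > max_nodes:
                return
            if any(cand is c for c in chosen):
                continue
            if all(
                abs(float(np.linalg.norm(cand.xyz - prev.xyz)) - dmat[site, ps]) <= tol
                for ps, prev in enumerate(chosen)
            ):
                chosen.append(cand)
                yield from backtrack(site + 1)
                chosen.pop()

    yield from backtrack(0)


def align_to_hypothesis(molecule: Molecule, hyp: PharmacophoreHypothesis) -> AlignmentResult:
    """Best rigid fit of a conformer ensemble onto a hypothesis.

    The fit score is the RMSD between matched feature centroids and the
    hypothesis sites after optimal superposition, minimized over conformers
    and feature assignments.  ``matched`` is True iff some complete
    kind-respecting assignment lands within the hypothesis tolerance.
    Unmatched molecules get an infinite fit score, never an exception.
    """
    if molecule.n_conformers == 0:
        raise ValueError(f"molecule {molecule.id!r} has no conformers")
    sites = hyp.site_array
    dmat = hyp.distance_matrix
    # distance pruning is run slightly loose so borderline assignments still
    # reach the RMSD test that decides the match
    prune_tol = 2.0 * hyp.tolerance
    best = AlignmentResult(UNMATCHED_SENTINEL, False, -1)
    for conf_id in range(molecule.n_conformers):
        feats = perceive_features(molecule, conf_id)
        for assignment in _assignments(feats, hyp.kinds, dmat, prune_tol):
            src = np.array([f.position for f in assignment])
            rmsd, rot, t = _kabsch(src, sites)
            if rmsd < best.fit_score:
                best = AlignmentResult(rmsd, rmsd <= hyp.tolerance, conf_id, rot, t)
    return best


def hypothesis_training_fit(
    hyp: PharmacophoreHypothesis,
    training: Sequence[tuple[Molecule, ActivityRecord]],
    unmatched_penalty: float = 1e6,
) -> float:
    """Mean alignment fit score of a hypothesis over a training set.

    Lower is better; unmatched compounds contribute *unmatched_penalty* so
    hypotheses that fail part of the training set sort last.
    """
    scores = []
    for mol, _ in training:
        res = align_to_hypothesis(mol, hyp)
        scores.append(res.fit_score if math.isfinite(res.fit_score) else unmatched_penalty)
    return float(np.mean(scores))


def rank_hypotheses(
    hypotheses: Sequence[PharmacophoreHypothesis],
    training: Sequence[tuple[Molecule, ActivityRecord]],
) -> list[tuple[float, PharmacophoreHypothesis]]:
    """Hypotheses sorted by training fit (best first), ties by label."""
    scored = [(hypothesis_training_fit(h, training), h) for h in hypotheses]
    scored.sort(key=lambda t: (t[0], t[1].label))
    return scored


# --------------------------------------------------------------------------
# descriptors + PLS regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Fixed rectilinear descriptor grid around the hypothesis sites."""

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    spacing: float = 2.0
    sigma: float = 1.0  # Gaussian occupancy width, Å

    @classmethod
    def around(cls, sites: np.ndarray, margin: float = 2.0, spacing: float = 2.0, sigma: float = 1.0) -> "GridSpec":
        lo = sites.min(axis=0) - margin
        hi = sites.max(axis=0) + margin
        shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(tuple(float(v) for v in lo), shape, spacing, sigma)

    @property
    def points(self) -> np.ndarray:
        ax = [np.arange(self.shape[i]) * self.spacing + self.origin[i] for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @property
    def n_descriptors(self) -> int:
        return int(np.prod(self.shape)) * len(FEATURE_KINDS)


def compute_descriptors(molecule: Molecule, hyp: PharmacophoreHypothesis, grid: GridSpec) -> tuple[np.ndarray, AlignmentResult]:
    """Per-kind Gaussian feature occupancies on the grid, in the hypothesis
    frame.  Unmatched molecules yield an all-zero vector."""
    align = align_to_hypothesis(molecule, hyp)
    x = np.zeros(grid.n_descriptors)
    if not align.matched:
        return x, align
    feats = perceive_features(molecule, align.aligned_conformer)
    pts = grid.points
    npts = pts.shape[0]
    for f in feats:
        moved = align.rotation @ f.xyz + align.translation
        channel = FEATURE_KINDS.index(f.kind)
        d2 = np.sum((pts - moved) ** 2, axis=1)
        x[channel * npts : (channel + 1) * npts] += np.exp(-d2 / (2.0 * grid.sigma**2))
    return x, align


@dataclass
class QsarModel:
    hypothesis: PharmacophoreHypothesis
    grid: GridSpec
    coefficients: np.ndarray  # linear weights over the descriptor vector
    intercept: float
    n_components: int
    training_ids: list[str]
    training_records: list[tuple[Molecule, ActivityRecord]] = field(repr=False, default_factory=list)
    fit_stats: dict = field(default_factory=dict)

    def predict_pic50_from_descriptors(self, x: np.ndarray) -> float:
        return float(x @ self.coefficients + self.intercept)


def _pls_linear_fit(x: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, float]:
    """Deterministic PLS fit collapsed to explicit linear form y ~ x @ coef + b."""
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, y.reshape(-1, 1))
    coef = pls.coef_.reshape(-1)
    b = float(pls.intercept_.reshape(-1)[0] - pls._x_mean @ coef)
    return coef, b


def fit_qsar(
    training: Sequence[tuple[Molecule, ActivityRecord]],
    hyp: PharmacophoreHypothesis,
    max_components: int = 5,
    grid: GridSpec | None = None,
) -> QsarModel:
    """Fit the 3D-QSAR on hypothesis-aligned grid descriptors.

    Requires >= 6 matched training compounds spanning >= 2 log units of
    activity.  The PLS component count (<= *max_components*) is chosen by
    leave-one-out cross-validated q2; the solver is deterministic, so
    refitting identical data reproduces coefficients bitwise.
    """
    if grid is None:
        grid = GridSpec.around(hyp.site_array)
    rows = []
    for mol, act in training:
        x, align = compute_descriptors(mol, hyp, grid)
        if align.matched:
            rows.append((mol, act, x))
        else:
            logger.warning("fit_qsar: training compound %s does not match %s", act.compound_id, hyp.label)
    if len(rows) < 6:
        raise ValueError(f"fit_qsar: only {len(rows)} of {len(training)} training compounds match {hyp.label}; need 6")
    y = np.array([act.pic50 for _, act, _ in rows])
    if y.max() - y.min() < 2.0:
        raise ValueError("fit_qsar: training activities span < 2 log units")
    x = np.vstack([xi for _, _, xi in rows])
    n = len(rows)
    cap = min(max_components, n - 2, int(np.linalg.matrix_rank(x - x.mean(axis=0))))
    cap = max(cap, 1)
    best_c, best_q2 = 1, -np.inf
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for c in range(1, cap + 1):
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            coef, b = _pls_linear_fit(x[mask], y[mask], c)
            press += (x[i] @ coef + b - y[i]) ** 2
        q2 = 1.0 - press / ss_tot
        if q2 > best_q2 + 1e-12:
            best_q2, best_c = q2, c
    coef, b = _pls_linear_fit(x, y, best_c)
    pred = x @ coef + b
    resid = pred - y
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    return QsarModel(
        hypothesis=hyp,
        grid=grid,
        coefficients=coef,
        intercept=b,
        n_components=best_c,
        training_ids=[act.compound_id for _, act, _ in rows],
        training_records=[(m, a) for m, a, _ in rows],
        fit_stats={"r2": r2, "rmse": rmse, "q2_loo": best_q2, "n_training": n},
    )


def predict_activity(model: QsarModel, molecule: Molecule) -> ActivityRecord:
    """Predict potency; unmatched molecules get a flagged worst-tier record.

    Predictions are clamped to the training pIC50 range — a simple domain-
    of-applicability guard, since the grid descriptor extrapolates poorly
    outside the span of the training chemotypes.  The worst tier for
    unmatched molecules is 10x the worst training IC50, so downstream
    normalization stays total over the candidate pool.
    """
    x, align = compute_descriptors(molecule, model.hypothesis, model.grid)
    if not align.matched:
        worst = max(a.ic50 for _, a in model.training_records)
        rec = ActivityRecord.from_ic50(molecule.id, 10.0 * worst, source="predicted")
        return replace(rec, matched=False)
    pic50 = model.predict_pic50_from_descriptors(x)
    y = [a.pic50 for _, a in model.training_records]
    pic50 = min(max(pic50, min(y)), max(y))
    return ActivityRecord.from_pic50(molecule.id, pic50, source="predicted")


def update_with_experimental(
    model: QsarModel,
    new_records: Sequence[tuple[Molecule, ActivityRecord]],
) -> QsarModel:
    """Feedback retraining: refit the same hypothesis and grid on the union
    of old and new measured records.

    Records identical to an existing (id, IC50) pair are dropped, so the
    update is idempotent; a duplicate id with a conflicting IC50 is an
    error.  The refit model's stats include the new compounds' in-sample
    residuals.
    """
    merged: dict[str, tuple[Molecule, ActivityRecord]] = {
        a.compound_id: (m, a) for m, a in model.training_records
    }
    new_ids = []
    for mol, act in new_records:
        if act.source != "measured":
            raise ValueError(f"update_with_experimental: {act.compound_id} is not a measured record")
        prev = merged.get(act.compound_id)
        if prev is not None:
            if not math.isclose(prev[1].ic50, act.ic50, rel_tol=1e-12):
                raise ValueError(
                    f"conflicting IC50 for {act.compound_id}: {prev[1].ic50} vs {act.ic50}"
                )
            continue
        merged[act.compound_id] = (mol, act)
        new_ids.append(act.compound_id)
    refit = fit_qsar(list(merged.values()), model.hypothesis, grid=model.grid)
    residuals = {}
    for cid in new_ids:
        mol, act = merged[cid]
        pred = predict_activity(refit, mol)
        residuals[cid] = pred.pic50 - act.pic50
    refit.fit_stats["new_residuals"] = residuals
    return refit


def classify_under_threshold(records: Sequence[ActivityRecord], threshold: float = 500.0) -> list[bool]:
    """True iff the predicted IC50 is strictly below *threshold* (nM)."""
    return [r.predicted_ic50 < threshold for r in records]
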