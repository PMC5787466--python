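"""Gaussian shape-overlay screening.

First reductive filter of the pipeline: every candidate is represented as a
sum of first-order atomic Gaussians (Grant–Pickup model, heavy atoms only),
rigid-body aligned onto each reference inhibitor, and scored with the shape
Tanimoto

    T = V_AB / (V_AA + V_BB - V_AB)

where V_XY is the total Gaussian overlap volume.  The overlay optimizer is
deterministic: volume-weighted centering, principal-axes alignment with the
four proper axis flips, then local rigid-body refinement of the best start.

Atomic Gaussians use amplitude p = 2.7 and width alpha chosen so each atom
Gaussian integrates to its hard-sphere volume; radii are either element vdW
radii or a uniform 1.7 Å carbon radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chemio import Molecule

logger = logging.getLogger("hopscreen")

__all__ = [
    "ShapeScore",
    "gaussian_params",
    "overlap_volume",
    "shape_overlap",
    "generate_conformer_ensemble",
    "shape_screen",
]

P_AMPLITUDE = 2.7
_PERIODIC = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class ShapeScore:
    candidate_id: str
    reference_id: str
    similarity: float
    best_conformer_index: int


# --------------------------------------------------------------------------
# Gaussian volume model
# --------------------------------------------------------------------------

def _alpha_for_radius(radius: np.ndarray) -> np.ndarray:
    """Width so that p * (pi/alpha)^{3/2} equals the sphere volume 4/3 pi r^3."""
    return np.pi * (3.0 * P_AMPLITUDE / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)


def gaussian_params(
    mol: Chem.Mol, conf_id: int = 0, uniform_radius: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinates and Gaussian widths for one conformer.

    With ``uniform_radius`` set, every atom uses that radius; otherwise
    element van der Waals radii are used.
    """
    conf = mol.GetConformer(conf_id)
    coords, radii = [], []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        coords.append([pos.x, pos.y, pos.z])
        if uniform_radius is not None:
            radii.append(uniform_radius)
        else:
            radii.append(_PERIODIC.GetRvdw(atom.GetAtomicNum()))
    coords = np.asarray(coords, dtype=float)
    alphas = _alpha_for_radius(np.asarray(radii, dtype=float))
    return coords, alphas


def overlap_volume(
    coords_a: np.ndarray,
    alphas_a: np.ndarray,
    coords_b: np.ndarray,
    alphas_b: np.ndarray,
) -> float:
    """First-order Gaussian overlap volume between two atom sets.

    Sum over atom pairs of the closed-form Gaussian product integral

        p^2 (pi/(a_i+a_j))^{3/2} exp(-a_i a_j / (a_i+a_j) * d_ij^2).
    """
    d2 = np.sum((coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1)
    asum = alphas_a[:, None] + alphas_b[None, :]
    k = np.exp(-(alphas_a[:, None] * alphas_b[None, :] / asum) * d2)
    return float(np.sum(P_AMPLITUDE**2 * k * (np.pi / asum) ** 1.5))


def _self_volume(coords: np.ndarray, alphas: np.ndarray) -> float:
    return overlap_volume(coords, alphas, coords, alphas)


def _principal_frame(coords: np.ndarray, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted centroid and principal axes (right-handed).

    Axis signs are fixed from the weighted third moment (skewness) of the
    distribution along each axis, so the frame is a deterministic function
    of the shape itself and identical for rigidly moved copies."""
    w = P_AMPLITUDE * (np.pi / alphas) ** 1.5
    center = np.average(coords, axis=0, weights=w)
    x = coords - center
    cov = (x * w[:, None]).T @ x / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    for k in range(2):
        proj = x @ axes[:, k]
        skew = float(np.sum(w * proj**3))
        if skew == 0.0:  # symmetric direction: fall back to extreme offset
            skew = float(proj[np.argmax(np.abs(proj))])
        if skew < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return center, axes


_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def _tanimoto(vab: float, vaa: float, vbb: float) -> float:
    return vab / (vaa + vbb - vab)


def shape_overlap(
    ref: Molecule,
    cand: Molecule,
    ref_conf: int = 0,
    cand_conf: int = 0,
    uniform_radius: float | None = None,
    refine: bool = True,
) -> float:
    """Shape Tanimoto in [0, 1] after rigid-body overlay optimization.

    Symmetric within optimizer tolerance and invariant to initial rigid
    transforms of either input.  Raises if either molecule lacks the
    requested conformer.
    """
    for m, c in ((ref, ref_conf), (cand, cand_conf)):
        if m.mol.GetNumConformers() <= c:
            raise ValueError(f"molecule {m.id!r} is missing conformer {c}")
    ca, aa = gaussian_params(ref.mol, ref_conf, uniform_radius)
    cb, ab = gaussian_params(cand.mol, cand_conf, uniform_radius)
    # the overlap functional is symmetric; run the optimizer in a canonical,
    # rotation-invariant argument order so both call directions share one
    # optimization path
    def order_key(coords: np.ndarray, alphas: np.ndarray, smiles: str):
        w = P_AMPLITUDE * (np.pi / alphas) ** 1.5
        x = coords - np.average(coords, axis=0, weights=w)
        cov = (x * w[:, None]).T @ x / w.sum()
        evals = np.sort(np.linalg.eigvalsh(cov))
        return (smiles, tuple(np.round(evals, 6)))

    if order_key(cb, ab, Chem.MolToSmiles(cand.mol)) < order_key(ca, aa, Chem.MolToSmiles(ref.mol)):
        ca, aa, cb, ab = cb, ab, ca, aa
    vaa = _self_volume(ca, aa)
    vbb = _self_volume(cb, ab)

    center_a, axes_a = _principal_frame(ca, aa)
    center_b, axes_b = _principal_frame(cb, ab)
    ca0 = (ca - center_a) @ axes_a  # reference in its principal frame

    def negative_overlap(x: np.ndarray, start: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = start @ rot.T + x[3:]
        return -overlap_volume(ca0, aa, moved, ab)

    vab = -np.inf
    coarse: list[tuple[float, np.ndarray, np.ndarray]] = []
    for flip in _FLIPS:
        cb0 = (cb - center_b) @ axes_b @ flip
        vab = max(vab, overlap_volume(ca0, aa, cb0, ab))
        if refine:
            # coarse local refinement from every flip, so the global optimum
            # is found whichever principal frame it sits in
            res = minimize(
                negative_overlap,
                np.zeros(6),
                args=(cb0,),
                method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 200},
            )
            coarse.append((-res.fun, cb0, res.x))
    if refine and coarse:
        # polish the two best coarse optima tightly; symmetric inputs then
        # land in the same basin regardless of overlay direction
        coarse.sort(key=lambda t: -t[0])
        for _, start, x0 in coarse[:2]:
            res = minimize(
                negative_overlap,
                x0,
                args=(start,),
                method="Powell",
                options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 1000},
            )
            vab = max(vab, -res.fun)

    sim = _tanimoto(vab, vaa, vbb)
    return float(min(max(sim, 0.0), 1.0))


# --------------------------------------------------------------------------
# conformer ensembles
# --------------------------------------------------------------------------

def generate_conformer_ensemble(
    molecule: Molecule,
    n_conformers: int = 100,
    seed: int = 7,
    rms_threshold: float = 0.5,
) -> Molecule:
    """Embed, minimize and RMSD-deduplicate up to *n_conformers* conformers.

    ETKDG embedding at a fixed seed, MMFF94 minimization, then greedy
    heavy-atom RMSD pruning at *rms_threshold* Å in energy order, so the
    ensemble is deterministic and its lowest-energy member is conformer 0.
    The molecule is rebuilt in canonical atom order first, so the ensemble
    depends only on the molecular graph, not on construction history.
    """
    canonical = Chem.MolFromSmiles(Chem.MolToSmiles(molecule.mol))
    if canonical is None:  # pragma: no cover - sanitized input
        raise ValueError(f"cannot canonicalize {molecule.id!r}")
    mol = Chem.AddHs(canonical)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        raise ValueError(f"conformer embedding failed for {molecule.id!r}")
    energies = []
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=1000, numThreads=1)
        energies = [e for _, e in results]
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=1000, numThreads=1)
        energies = [e for _, e in results]
    mol = Chem.RemoveHs(mol)
    order = sorted(range(len(ids)), key=lambda i: (energies[i], i))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            rms = rdMolAlign.GetBestRMS(mol, mol, prbId=ids[i], refId=ids[j])
            if rms < rms_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    for rank, i in enumerate(kept):
        conf = Chem.Conformer(mol.GetConformer(ids[i]))
        conf.SetId(rank)
        out.AddConformer(conf, assignId=True)
    result = molecule.copy()
    result.mol = out
    return result


# --------------------------------------------------------------------------
# screening
# --------------------------------------------------------------------------

def shape_screen(
    library: Sequence[Molecule],
    references: Sequence[Molecule],
    n_conformers: int = 100,
    keep_threshold: float = 0.5,
    seed: int = 7,
    uniform_radius: float | None = None,
) -> tuple[list[ShapeScore], str | None]:
    """Screen a library against reference inhibitors by best shape overlay.

    For each candidate the similarity is the maximum over all (reference,
    candidate-conformer) pairs; candidates at or above *keep_threshold*
    survive.  Returns the survivor scores and the id of the reference that
    retained the most candidates (the reference selected for downstream
    filtering).  Library molecules without conformers get an ensemble
    generated here; references use their first conformer.
    """
    if not references:
        raise ValueError("shape_screen requires at least one reference")
    survivors: list[ShapeScore] = []
    per_ref: dict[str, int] = {r.id: 0 for r in references}
    for cand in library:
        ens = cand
        if cand.n_conformers == 0:
            try:
                ens = generate_conformer_ensemble(cand, n_conformers, seed=seed)
            except ValueError:
                logger.warning("shape_screen: skipping %s (embedding failed)", cand.id)
                continue
        best_sim, best_ref, best_conf = -1.0, None, -1
        for ref in references:
            for ci in range(ens.n_conformers):
                sim = shape_overlap(ref, ens, 0, ci, uniform_radius=uniform_radius)
                if sim > best_sim:
                    best_sim, best_ref, best_conf = sim, ref.id, ci
        if best_sim >= keep_threshold and best_ref is not None:
            survivors.append(ShapeScore(cand.id, best_ref, best_sim, best_conf))
            per_ref[best_ref] += 1
    top_ref = None
    if survivors:
        top_ref = max(per_ref.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return survivors, top_ref
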