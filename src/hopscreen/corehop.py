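"""Core separation and combinatorial core-replacement (scaffold hopping).

A parent inhibitor is decomposed into its central scaffold — the Murcko-style
framework of ring systems plus inter-ring linkers — and its peripheral
"edges": the acyclic substituents cut at exocyclic single bonds.  New hybrid
ligands are generated by fusing the edges of a parent onto replacement cores
drawn from a core library, followed by a structural-alert screen and a
force-field geometry cleanup.

Attachment points are encoded as dummy atoms; fragments are recombined with
``Chem.molzip`` using matched isotope labels, so the decomposition is exactly
invertible (reassembling core + edges regenerates the parent).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Molecule

logger = logging.getLogger("hopscreen")

_MOLZIP = Chem.MolzipParams()
_MOLZIP.label = Chem.MolzipLabel.Isotope

__all__ = [
    "FragmentSet",
    "HybridCandidate",
    "separate_core",
    "reassemble",
    "enumerate_hybrids",
    "filter_reactive",
    "cleanup_geometry",
]


@dataclass
class FragmentSet:
    """Decomposition of a parent into core scaffold plus edge fragments.

    The core carries ``k >= 1`` dummy-atom attachment points (isotope labels
    1..k); each edge carries exactly one dummy with the matching label, so
    the pairing of core attachment points to edges is encoded structurally.
    """

    parent_id: str
    core: Chem.Mol
    edges: list[Chem.Mol]

    @property
    def n_attachment_points(self) -> int:
        return sum(1 for a in self.core.GetAtoms() if a.GetAtomicNum() == 0)


@dataclass
class HybridCandidate:
    id: str
    molecule: Molecule
    core_origin: str
    edge_origin: list[str]
    flagged: bool = False
    flag_reason: str = ""


def _framework_atoms(mol: Chem.Mol) -> set[int]:
    """Murcko-style framework: iteratively prune terminal atoms attached by
    acyclic single bonds.  Exocyclic multiply-bonded atoms (e.g. carbonyl O)
    stay with the framework because their bond cannot be cut."""
    keep = set(range(mol.GetNumAtoms()))
    changed = True
    while changed:
        changed = False
        for idx in sorted(keep):
            atom = mol.GetAtomWithIdx(idx)
            if atom.IsInRing():
                continue
            nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetIdx() in keep]
            if len(nbrs) == 1:
                bond = mol.GetBondBetweenAtoms(idx, nbrs[0])
                if bond.GetBondType() == Chem.BondType.SINGLE:
                    keep.discard(idx)
                    changed = True
    return keep


def separate_core(parent: Molecule) -> FragmentSet:
    """Split a parent into its ring-containing scaffold and acyclic edges.

    Raises ``ValueError('no separable core')`` for acyclic parents.  Parents
    with no acyclic periphery yield a FragmentSet whose core is the parent
    itself only if at least one edge exists; a bare scaffold raises too,
    since there is nothing to transplant.
    """
    mol = parent.mol
    if mol.GetRingInfo().NumRings() == 0:
        raise ValueError(f"no separable core: {parent.id} is acyclic")
    framework = _framework_atoms(mol)
    cut_bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in framework) != (j in framework):
            cut_bonds.append(bond.GetIdx())
    if not cut_bonds:
        raise ValueError(f"no separable core: {parent.id} has no acyclic periphery")
    labels = [(k + 1, k + 1) for k in range(len(cut_bonds))]
    frag = Chem.FragmentOnBonds(mol, cut_bonds, addDummies=True, dummyLabels=labels)
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    core = None
    edges = []
    for piece in pieces:
        heavy_idx = [a.GetIdx() for a in piece.GetAtoms() if a.GetAtomicNum() > 0]
        if any(piece.GetAtomWithIdx(i).IsInRing() for i in heavy_idx):
            if core is not None:
                # two ring fragments can only appear if the framework were
                # disconnected, which pruning never produces
                raise AssertionError("framework unexpectedly disconnected")
            core = piece
        else:
            edges.append(piece)
    if core is None:  # pragma: no cover - guarded by NumRings check
        raise ValueError(f"no separable core: {parent.id}")
    return FragmentSet(parent_id=parent.id, core=core, edges=edges)


def _relabel_dummies(mol: Chem.Mol, new_labels: list[int]) -> Chem.Mol:
    """Return a copy with dummy-atom isotope labels rewritten in canonical
    dummy order."""
    out = Chem.RWMol(mol)
    dummies = [a.GetIdx() for a in out.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != len(new_labels):
        raise ValueError("label count mismatch")
    # order dummies deterministically by canonical rank
    ranks = list(Chem.CanonicalRankAtoms(mol, includeIsotopes=False))
    dummies.sort(key=lambda i: ranks[i])
    for idx, lab in zip(dummies, new_labels):
        out.GetAtomWithIdx(idx).SetIsotope(lab)
    return out.GetMol()


def reassemble(fragment_set: FragmentSet) -> Molecule:
    """Fuse core and edges back together via their matched dummy labels."""
    combined = fragment_set.core
    for edge in fragment_set.edges:
        combined = Chem.CombineMols(combined, edge)
    merged = Chem.molzip(combined, _MOLZIP)
    Chem.SanitizeMol(merged)
    return Molecule(id=fragment_set.parent_id, mol=merged, source="fused")


def enumerate_hybrids(
    fragment_sets: list[FragmentSet],
    core_library: list[Molecule],
    max_products: int = 10000,
    pool_edges: bool = False,
) -> list[HybridCandidate]:
    """Fuse edge multisets onto every compatible replacement core.

    By default each parent's own edge multiset is used; a core is compatible
    when its attachment-point count equals the edge count.  With
    ``pool_edges=True`` the edges of all parents are pooled (the ligand-pool
    step) and every distinct k-permutation of pooled edges is fused onto
    each k-point core, which is what expands three parents and a few dozen
    cores into thousands of raw products.

    Attachment points are ordered by canonical atom rank and edges assigned
    in sorted (canonical SMILES) order; all permutations are explored when a
    core has <= 4 points.  Products are deduplicated by canonical SMILES and
    truncated deterministically (lexicographic by canonical SMILES) at
    *max_products*.
    """
    if not core_library:
        logger.warning("enumerate_hybrids: empty core library")
        return []
    products: dict[str, HybridCandidate] = {}

    def fuse(core_mol: Molecule, edges: list[Chem.Mol], parent_ids: list[str]) -> None:
        k = len(edges)
        combined = _relabel_dummies(core_mol.mol, list(range(1, k + 1)))
        try:
            for pos, edge in enumerate(edges, start=1):
                combined = Chem.CombineMols(combined, _relabel_dummies(edge, [pos]))
            fused = Chem.molzip(combined, _MOLZIP)
            Chem.SanitizeMol(fused)
        except Exception:
            return
        smi = Chem.MolToSmiles(fused)
        if smi in products:
            return
        products[smi] = HybridCandidate(
            id="",
            molecule=Molecule(id="", mol=fused, source="fused"),
            core_origin=core_mol.id,
            edge_origin=sorted(set(parent_ids)),
        )

    if pool_edges:
        pooled = [
            (edge, fs.parent_id)
            for fs in fragment_sets
            for edge in sorted(fs.edges, key=lambda e: Chem.MolToSmiles(e))
        ]
        for core_mol in core_library:
            k = sum(1 for a in core_mol.mol.GetAtoms() if a.GetAtomicNum() == 0)
            if k == 0 or k > len(pooled) or k > 4:
                continue
            for combo in itertools.permutations(range(len(pooled)), k):
                edges = [pooled[i][0] for i in combo]
                fuse(core_mol, edges, [pooled[i][1] for i in combo])
    else:
        for fs in fragment_sets:
            k = len(fs.edges)
            if k == 0:
                continue
            sorted_edges = sorted(fs.edges, key=lambda e: Chem.MolToSmiles(e))
            for core_mol in core_library:
                n_points = sum(1 for a in core_mol.mol.GetAtoms() if a.GetAtomicNum() == 0)
                if n_points != k:
                    continue
                orders = itertools.permutations(range(k)) if k <= 4 else [tuple(range(k))]
                for order in orders:
                    fuse(core_mol, [sorted_edges[i] for i in order], [fs.parent_id])
    ordered = [products[smi] for smi in sorted(products)][:max_products]
    for i, cand in enumerate(ordered, start=1):
        cand.id = f"hyb{i:05d}"
        cand.molecule.id = cand.id
    return ordered


# --------------------------------------------------------------------------
# reactive-group screening
# --------------------------------------------------------------------------

# fixed structural-alert dictionary; each entry is (reason, SMARTS)
_ALERTS = (
    ("acid halide", "[CX3](=[OX1])[F,Cl,Br,I]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("epoxide", "[OX2r3]1[#6r3][#6r3]1"),
    ("aziridine", "[NX3r3]1[#6r3][#6r3]1"),
    ("alkyl halide", "[CX4][Cl,Br,I]"),
    ("anhydride", "[CX3](=[OX1])[OX2][CX3](=[OX1])"),
    ("peroxide", "[OX2][OX2]"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    (
        "doubly activated Michael acceptor",
        "[CX3]=[CX3]([$([CX3]=[OX1]),$(C#N),$([SX4](=O)(=O)),$([NX3+](=O)[O-])])"
        "[$([CX3]=[OX1]),$(C#N),$([SX4](=O)(=O)),$([NX3+](=O)[O-])]",
    ),
)
_ALERT_PATTERNS = [(reason, Chem.MolFromSmarts(s)) for reason, s in _ALERTS]


def filter_reactive(
    candidates: list[HybridCandidate],
) -> tuple[list[HybridCandidate], list[tuple[HybridCandidate, str]]]:
    """Partition candidates into (passed, rejected-with-reason).

    The rejection reason names the first matched alert pattern; the
    partition is exhaustive and disjoint.
    """
    passed: list[HybridCandidate] = []
    rejected: list[tuple[HybridCandidate, str]] = []
    for cand in candidates:
        reason = None
        for name, patt in _ALERT_PATTERNS:
            if cand.molecule.mol.HasSubstructMatch(patt):
                reason = name
                break
        if reason is None:
            passed.append(cand)
        else:
            rejected.append((cand, reason))
    return passed, rejected


# --------------------------------------------------------------------------
# geometry cleanup
# --------------------------------------------------------------------------

def cleanup_geometry(candidate: HybridCandidate, seed: int = 7, max_iters: int = 2000) -> HybridCandidate:
    """Embed one 3D conformer and minimize it with MMFF94.

    Pure and deterministic under a fixed seed: the input candidate is never
    mutated, and the molecule is rebuilt in canonical atom order before
    embedding so the result depends only on the molecular graph.  After
    three failed embedding attempts the returned candidate is flagged
    (``flagged=True``) and should be excluded downstream.
    """
    canonical = Chem.MolFromSmiles(Chem.MolToSmiles(candidate.molecule.mol))
    mol = Chem.AddHs(canonical)
    params = AllChem.ETKDGv3()
    conf_id = -1
    for attempt in range(3):
        params.randomSeed = seed + attempt
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        logger.warning("embedding failed for %s", candidate.id)
        return replace(candidate, flagged=True, flag_reason="embedding failure")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=max_iters, nonBondedThresh=100.0)
    else:  # fall back to UFF for exotic atoms
        AllChem.UFFOptimizeMolecule(mol, maxIters=max_iters)
    mol = Chem.RemoveHs(mol)
    out = Molecule(id=candidate.molecule.id, mol=mol, source=candidate.molecule.source)
    return replace(candidate, molecule=out)
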