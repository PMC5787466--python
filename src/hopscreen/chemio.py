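"""Molecule model, SMILES/SDF I/O and physicochemical property estimation.

Every downstream stage of the screening pipeline works on :class:`Molecule`,
a thin identified wrapper around a sanitized RDKit molecule.  Property
estimation backs the druglikeness gate: logP is the Crippen
atom-contribution estimate, aqueous solubility follows the ESOL linear
model, and Caco-2 permeability / primary-metabolite counts are simple,
documented QSPR surrogates (see docs/methods.md) chosen so the whole
pipeline runs on open descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

logger = logging.getLogger("hopscreen")
RDLogger.DisableLog("rdApp.*")  # parse failures are reported through our own log

__all__ = [
    "Molecule",
    "MoleculeProperties",
    "parse_molecules",
    "write_molecules",
    "compute_properties",
]


@dataclass
class Molecule:
    """An identified, sanitized chemical structure.

    Parameters
    ----------
    id:
        Unique identifier within a library.
    mol:
        Sanitized ``rdkit.Chem.Mol``; may carry 3D conformers (Å).
    source:
        Provenance tag: ``parsed``, ``generated`` or ``fused``.
    """

    id: str
    mol: Chem.Mol
    source: str = "parsed"

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def copy(self) -> "Molecule":
        return replace(self, mol=Chem.Mol(self.mol))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule(id={self.id!r}, smiles={self.smiles!r}, conformers={self.n_conformers})"


def from_smiles(smiles: str, mol_id: str, source: str = "parsed") -> Molecule:
    """Parse a single SMILES into a sanitized Molecule.

    Raises ``ValueError`` on invalid input; a parse failure never yields a
    Molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES for {mol_id!r}: {smiles!r}")
    return Molecule(id=mol_id, mol=mol, source=source)


def parse_molecules(path: str | Path, format: str = "smiles") -> list[Molecule]:
    """Read molecules from a SMILES or SDF (V2000) file.

    SMILES files carry one record per line (``SMILES [id]``); lines starting
    with ``#`` are treated as comments.  Invalid records are skipped and
    logged with their record index; the returned list preserves file order.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read molecule file: {path}")
    mols: list[Molecule] = []
    n_skipped = 0
    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{lineno}"
            rdmol = Chem.MolFromSmiles(smi)
            if rdmol is None:
                n_skipped += 1
                logger.warning("skipping invalid SMILES at %s:%d", path, lineno)
                continue
            mols.append(Molecule(id=mol_id, mol=rdmol))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for idx, rdmol in enumerate(supplier):
            if rdmol is None:
                n_skipped += 1
                logger.warning("skipping invalid SDF record %d in %s", idx, path)
                continue
            mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"{path.stem}_{idx}"
            mols.append(Molecule(id=mol_id, mol=rdmol))
    else:
        raise ValueError(f"unknown format: {format!r}")
    if not mols:
        logger.warning("no valid records in %s (%d skipped)", path, n_skipped)
    return mols


def write_molecules(mols: Sequence[Molecule], path: str | Path, format: str = "smiles") -> int:
    """Write molecules to SMILES or SDF V2000; returns the record count.

    Round-trip safe: re-parsing the file reproduces each molecule's canonical
    structure.  Writing a conformer-less molecule as SDF raises, naming the
    offending id, because SDF output here is 3D.
    """
    path = Path(path)
    if format == "smiles":
        lines = [f"{m.smiles}\t{m.id}" for m in mols]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for m in mols:
                if m.n_conformers == 0:
                    raise ValueError(f"molecule {m.id!r} has no conformer; cannot write 3D SDF")
                out = Chem.Mol(m.mol)
                out.SetProp("_Name", m.id)
                writer.write(out)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format: {format!r}")
    return len(mols)


# --------------------------------------------------------------------------
# property estimation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeProperties:
    """Physicochemical descriptor record used by the druglikeness gate.

    ``mw`` is the average (isotope-abundance weighted) molecular weight in
    g/mol; ``logs`` is log10 of aqueous solubility in mol/L (ESOL);
    ``caco2_perm`` is a Caco-2 apparent-permeability estimate in nm/s.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float
    logs: float
    caco2_perm: float
    n_primary_metabolites: int


# Soft metabolic sites: benzylic/allylic C-H, phenol, aniline N-H, ester,
# thioether.  A crude but monotone surrogate for a primary-metabolite count.
_METABOLIC_SMARTS = (
    ("benzylic CH", "[CX4;!H0;$([CX4][c])]"),
    ("allylic CH", "[CX4;!H0;$([CX4][CX3]=[CX3])]"),
    ("phenol", "[OX2H][c]"),
    ("aniline NH", "[NX3;H1,H2][c]"),
    ("ester", "[CX3](=[OX1])[OX2][#6]"),
    ("thioether", "[SX2]([#6])[#6]"),
)
_METABOLIC_PATTERNS = [(name, Chem.MolFromSmarts(s)) for name, s in _METABOLIC_SMARTS]


def _count_metabolic_sites(mol: Chem.Mol) -> int:
    seen: set[tuple[str, int]] = set()
    for name, patt in _METABOLIC_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            seen.add((name, match[0]))
    return len(seen)


def compute_properties(molecule: Molecule) -> MoleculeProperties:
    """Compute the full descriptor record for a sanitized molecule.

    Deterministic: equal molecules yield bitwise-equal records.
    """
    mol = molecule.mol
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = rdMolDescriptors.CalcNumHBA(mol)
    rotb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    aromatic_proportion = arom / heavy if heavy else 0.0
    # ESOL (Delaney) refit: logS from logP, MW, rotatable bonds, aromatic proportion
    logs = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * aromatic_proportion
    # linear QSPR surrogate for Caco-2 permeability on TPSA and donor count
    caco2 = 10.0 ** (4.0 - 0.018 * tpsa - 0.065 * hbd)
    return MoleculeProperties(
        mw=mw,
        logp=logp,
        hbd=hbd,
        hba=hba,
        rotatable_bonds=rotb,
        tpsa=tpsa,
        logs=logs,
        caco2_perm=caco2,
        n_primary_metabolites=_count_metabolic_sites(mol),
    )
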