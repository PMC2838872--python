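"""Pocket extraction from PDB structures and partial-charge labeling.

A binding pocket is defined as every polymer (protein) heavy atom situated
at less than R Å of any atom of the bound ligand; the ligand's own atoms are
never part of the pocket.  R defaults to 5.3 Å, which is a good general
cutoff, with useful behaviour for R anywhere between about 4.5 and 8 Å.

Atom labels are scalar partial charges looked up in a :class:`ChargeTable`
keyed by (residue name, atom name), with a wildcard residue ``*`` for
backbone atoms and a default for unknown keys.  The shipped table contains
*representative* united-atom charges for standard amino-acid heavy atoms; it
is deliberately small and user-replaceable via a ``resname,atomname,charge``
CSV — the similarity measure only needs a consistent scalar label, and the
label scale λ is learned per dataset anyway.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .pocket import Pocket

__all__ = [
    "AtomRecord",
    "StructureRecord",
    "ChargeTable",
    "read_pdb",
    "extract_pocket",
    "assign_charges",
]

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    element: str
    name: str
    res_name: str
    res_seq: int
    chain: str
    pos: tuple[float, float, float]
    het: bool  # True for HETATM (ligands, cofactors), False for polymer atoms


@dataclasses.dataclass(frozen=True)
class StructureRecord:
    """Flat list of atoms from a PDB file (waters removed, altlocs resolved)."""

    atoms: tuple[AtomRecord, ...]
    id: str


def read_pdb(path: str | Path) -> StructureRecord:
    """Read ATOM/HETATM records from a PDB file.

    Waters are excluded; alternate locations are resolved to the highest
    occupancy (ties to the first altloc in file order).
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse PDB file: {exc}") from exc
    st.remove_alternative_conformations()  # keeps the highest-occupancy altloc
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            het = res.het_flag == "H"
            for atom in res:
                if not np.all(np.isfinite([atom.pos.x, atom.pos.y, atom.pos.z])):
                    raise ValueError(f"{path}: non-finite coordinates in {res.name}")
                atoms.append(
                    AtomRecord(
                        element=atom.element.name,
                        name=atom.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain=chain.name,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        het=het,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return StructureRecord(atoms=tuple(atoms), id=path.stem)


def extract_pocket(
    s: StructureRecord,
    ligand_resname: str,
    ligand_chain: str | None = None,
    ligand_resseq: int | None = None,
    radius: float = 5.3,
    keep_hydrogens: bool = False,
) -> Pocket:
    """All polymer atoms at less than ``radius`` Å of any atom of the ligand.

    The ligand is identified by residue name and, optionally, chain and
    residue number; with several matching copies and no residue number, the
    first by file order is used (with a warning).  Hydrogens are excluded by
    default (crystal structures rarely resolve them).  The inequality is
    strict (< R).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig_keys = []
    for a in s.atoms:
        if a.res_name != ligand_resname:
            continue
        if ligand_chain is not None and a.chain != ligand_chain:
            continue
        if ligand_resseq is not None and a.res_seq != ligand_resseq:
            continue
        key = (a.chain, a.res_seq)
        if key not in lig_keys:
            lig_keys.append(key)
    if not lig_keys:
        raise ValueError(f"ligand not found: {ligand_resname}")
    if len(lig_keys) > 1 and ligand_resseq is None:
        logger.warning(
            "%d copies of ligand %s; using %s %d",
            len(lig_keys), ligand_resname, *lig_keys[0],
        )
    chain, seq = lig_keys[0]
    lig = np.array(
        [a.pos for a in s.atoms
         if a.res_name == ligand_resname and a.chain == chain and a.res_seq == seq]
    )
    sel = [
        a
        for a in s.atoms
        if not a.het
        and (keep_hydrogens or a.element not in ("H", "D"))
    ]
    coords = np.array([a.pos for a in sel]).reshape(-1, 3)
    if coords.size:
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        within = d2.min(axis=1) < radius * radius
    else:
        within = np.zeros(0, dtype=bool)
    if not within.any():
        raise ValueError(f"no atoms within R = {radius} Å of {ligand_resname}")
    return Pocket(
        coords=coords[within],
        id=f"{s.id}_{ligand_resname}",
        ligand_class=ligand_resname,
    )


@dataclasses.dataclass(frozen=True)
class ChargeTable:
    """(residue name, atom name) → partial charge, with wildcard and default.

    Lookup order: exact (resname, atomname), then ("*", atomname) for
    residue-independent backbone atoms, then ``default``.
    """

    mapping: dict[tuple[str, str], float]
    default: float = 0.0

    def lookup(self, res_name: str, atom_name: str) -> float:
        for key in ((res_name, atom_name), ("*", atom_name)):
            if key in self.mapping:
                return self.mapping[key]
        logger.warning("no charge for %s %s; using default %g",
                       res_name, atom_name, self.default)
        return self.default

    @classmethod
    def from_csv(cls, path: str | Path, default: float = 0.0) -> "ChargeTable":
        mapping: dict[tuple[str, str], float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("resname"):
                continue
            parts = [f.strip() for f in line.split(",")]
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected resname,atomname,charge")
            charge = float(parts[2])
            if not np.isfinite(charge):
                raise ValueError(f"{path}:{lineno}: non-finite charge")
            mapping[(parts[0], parts[1])] = charge
        return cls(mapping=mapping, default=default)

    @classmethod
    def default_table(cls) -> "ChargeTable":
        """The shipped representative united-atom charge table."""
        with resources.as_file(
            resources.files("pocketkernel.data") / "charges_ua.csv"
        ) as p:
            return cls.from_csv(p)


def assign_charges(p: Pocket, s: StructureRecord, table: ChargeTable) -> Pocket:
    """Label each pocket atom with its table charge; geometry unchanged.

    Pocket atoms are traced back to structure records by their coordinates
    (the pocket was cut from this same structure). Idempotent.
    """
    index = {
        tuple(round(c, 4) for c in a.pos): (a.res_name, a.name) for a in s.atoms
    }
    labels = np.empty(p.n_atoms)
    for i, xyz in enumerate(p.coords):
        key = tuple(round(float(c), 4) for c in xyz)
        if key not in index:
            raise ValueError(f"pocket atom {i} not found in structure {s.id}")
        labels[i] = table.lookup(*index[key])
    return p.with_labels(labels)
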