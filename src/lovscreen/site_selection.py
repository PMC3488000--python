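"""Chromophore-proximity selection of mutagenesis target residues.

Given a protein structure with a bound chromophore (e.g. the FMN
cofactor buried in a LOV domain), rank residues by their minimum
heavy-atom distance to the ligand and report the ones inside a cutoff
shell.  Saturation-mutagenesis campaigns on fluorescent proteins
typically target the residues lining the chromophore cavity — here the
0.3 nm first shell plus selected 0.4 nm neighbours — because those are
the positions whose side chains can perturb the photophysics.

Distances are reported in nanometres at the interface (1 nm = 10 Å);
coordinates stay in Ångström internally, matching the PDB format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "ResidueModel",
    "StructureModel",
    "ProximityHit",
    "StructureError",
    "parse_structure",
    "residues_within",
    "proximity_shells",
]

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})
_WATER_NAMES = frozenset({"HOH", "WAT"})


class StructureError(ValueError):
    """The structure cannot support a proximity analysis."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class ResidueModel:
    chain: str
    number: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def identifier(self) -> str:
        return f"{self.chain}:{self.name}{self.number}{self.icode}".rstrip()


@dataclass(frozen=True)
class StructureModel:
    """Protein residues plus the ligand atoms selected by residue name."""

    residues: tuple[ResidueModel, ...]
    ligand: tuple[Atom, ...]
    ligand_name: str


@dataclass(frozen=True)
class ProximityHit:
    """A residue within a distance shell of the ligand."""

    chain: str
    residue_number: int
    icode: str
    residue_name: str
    min_distance_nm: float
    shell: Literal["inner", "outer"] | None = None


def _first_altloc(bio_atom):
    """Resolve a possibly disordered atom to its first conformer."""
    if bio_atom.is_disordered():
        first_id = sorted(bio_atom.disordered_get_id_list())[0]
        return bio_atom.disordered_get(first_id)
    return bio_atom


def _to_atom(bio_atom) -> Atom:
    x, y, z = (float(v) for v in bio_atom.coord)
    element = (bio_atom.element or "").strip().upper()
    return Atom(name=bio_atom.get_name(), element=element, coord=(x, y, z))


def parse_structure(pdb_text: str, ligand_name: str = "FMN") -> StructureModel:
    """Parse fixed-column PDB text into a proximity-ready model.

    Only the first model is read; disordered atoms keep their first
    conformer (lowest altloc identifier); waters are dropped.  Raises
    :class:`StructureError` when no atom belongs to ``ligand_name``.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError("no models found in PDB text") from None

    residues: list[ResidueModel] = []
    ligand_atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            if resname in _WATER_NAMES:
                continue
            # Iterating the residue yields DisorderedAtom wrappers for
            # altloc'd atoms; resolve each to its first conformer.
            atoms = tuple(_to_atom(_first_altloc(a)) for a in residue)
            if resname == ligand_name:
                ligand_atoms.extend(atoms)
            elif hetflag.strip() == "":
                residues.append(
                    ResidueModel(
                        chain=chain.id,
                        number=int(resseq),
                        icode=icode.strip(),
                        name=resname,
                        atoms=atoms,
                    )
                )
    if not ligand_atoms:
        raise StructureError(f"no atoms found for ligand {ligand_name!r}")
    for atom in ligand_atoms + [a for r in residues for a in r.atoms]:
        if not all(np.isfinite(atom.coord)):
            raise StructureError(f"non-finite coordinates on atom {atom.name}")
    return StructureModel(
        residues=tuple(residues), ligand=tuple(ligand_atoms), ligand_name=ligand_name
    )


def _heavy_coords(atoms: tuple[Atom, ...]) -> np.ndarray:
    coords = [a.coord for a in atoms if a.element not in _HYDROGEN_ELEMENTS]
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def residues_within(
    model: StructureModel, cutoff_nm: float
) -> list[ProximityHit]:
    """Residues whose minimum heavy-atom distance to the ligand is <= cutoff.

    Hydrogens (and deuteriums) are excluded on both sides.  Hits are
    returned sorted by increasing distance.
    """
    if cutoff_nm <= 0:
        raise StructureError("cutoff must be positive")
    if not model.residues:
        raise StructureError("structure contains no protein residues")
    ligand_xyz = _heavy_coords(model.ligand)
    if ligand_xyz.size == 0:
        raise StructureError("ligand has no heavy atoms")

    hits: list[ProximityHit] = []
    for residue in model.residues:
        res_xyz = _heavy_coords(residue.atoms)
        if res_xyz.size == 0:
            continue
        min_a = float(cdist(res_xyz, ligand_xyz).min())
        min_nm = min_a / 10.0
        if min_nm <= cutoff_nm:
            hits.append(
                ProximityHit(
                    chain=residue.chain,
                    residue_number=residue.number,
                    icode=residue.icode,
                    residue_name=residue.name,
                    min_distance_nm=min_nm,
                )
            )
    hits.sort(key=lambda h: h.min_distance_nm)
    return hits


def proximity_shells(
    model: StructureModel, inner_nm: float = 0.3, outer_nm: float = 0.4
) -> list[ProximityHit]:
    """Label ligand-proximal residues as inner (<= inner) or outer (<= outer).

    The inner shell is always a subset of the outer shell.
    """
    if not 0 < inner_nm <= outer_nm:
        raise StructureError("require 0 < inner_nm <= outer_nm")
    hits = residues_within(model, outer_nm)
    return [
        ProximityHit(
            chain=h.chain,
            residue_number=h.residue_number,
            icode=h.icode,
            residue_name=h.residue_name,
            min_distance_nm=h.min_distance_nm,
            shell="inner" if h.min_distance_nm <= inner_nm else "outer",
        )
        for h in hits
    ]
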