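"""Chain/annotation I/O.

Reads protein chains from PDB files into a light internal model (heavy atoms
only, plain integer author numbering) and reads/writes the tabular side files
used throughout the pipeline: TM-helix annotations, residue-numbering offsets
and contact tables.

The internal model deliberately stores nothing but residue positions, residue
names and per-atom coordinates: every downstream feature is a function of
coordinates alone.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .errors import AnnotationError, ChainNotFoundError, PdbFormatError

__all__ = [
    "StructureSource",
    "ResidueRecord",
    "ChainStructure",
    "HelixAnnotation",
    "read_pdb_chain",
    "read_only_chain",
    "write_pdb",
    "read_helix_annotation",
    "write_helix_annotation",
    "read_offset_table",
    "apply_offset",
]


class StructureSource(str, enum.Enum):
    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"
    SYNTHETIC = "synthetic"


@dataclasses.dataclass
class ResidueRecord:
    """One residue: integer position, 3-letter name, heavy atoms by name.

    Atom coordinates are float64 arrays of shape (3,), in Angstrom.
    Hydrogens are never stored.
    """

    position: int
    resname: str
    atoms: Dict[str, np.ndarray]

    def heavy_coords(self) -> np.ndarray:
        """All heavy-atom coordinates as an (M, 3) array, in insertion order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack(list(self.atoms.values()))

    def get(self, name: str) -> Optional[np.ndarray]:
        return self.atoms.get(name)


@dataclasses.dataclass
class ChainStructure:
    """Position-ordered residues of one chain plus a provenance tag."""

    chain_id: str
    residues: List[ResidueRecord]
    source: StructureSource = StructureSource.EXPERIMENTAL

    def __post_init__(self) -> None:
        if not self.residues:
            raise PdbFormatError(f"chain {self.chain_id!r} has no residues")
        pos = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise PdbFormatError(
                f"chain {self.chain_id!r}: residue positions not strictly increasing"
            )
        self._by_position = {r.position: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> Optional[ResidueRecord]:
        return self._by_position.get(position)

    def positions(self) -> List[int]:
        return [r.position for r in self.residues]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        """Rigidly transform every atom: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        residues = [
            ResidueRecord(
                r.position,
                r.resname,
                {n: rotation @ c + translation for n, c in r.atoms.items()},
            )
            for r in self.residues
        ]
        return ChainStructure(self.chain_id, residues, self.source)


@dataclasses.dataclass
class HelixAnnotation:
    """TM helix segments of one chain as inclusive (start, end) ranges."""

    chain_id: str
    segments: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for start, end in segs:
            if start > end:
                raise AnnotationError(
                    f"chain {self.chain_id!r}: segment start {start} > end {end}"
                )
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"chain {self.chain_id!r}: overlapping helix segments"
                )
        self.segments = segs
        if self.tm_length() <= 0:
            raise AnnotationError(f"chain {self.chain_id!r}: empty annotation")

    def tm_length(self) -> int:
        """L: combined residue count of the TM helices."""
        return sum(e - s + 1 for s, e in self.segments)

    def helix_of(self, position: int) -> Optional[int]:
        """1-based index of the helix containing ``position``, else None."""
        for idx, (s, e) in enumerate(self.segments, start=1):
            if s <= position <= e:
                return idx
        return None

    def tm_positions(self) -> List[int]:
        return [p for s, e in self.segments for p in range(s, e + 1)]


# -- element inference for the atoms this package writes -----------------

_ELEMENTS = {"N": "N", "O": "O", "S": "S"}


def _element_for(atom_name: str) -> str:
    stripped = atom_name.strip()
    if len(stripped) <= 1 or stripped[0] == "C":
        return _ELEMENTS.get(stripped[:1], "C")
    return _ELEMENTS.get(stripped[0], "C")


def read_pdb_chain(
    path: str | Path,
    chain_id: str,
    source: StructureSource = StructureSource.EXPERIMENTAL,
) -> ChainStructure:
    """Read one chain from a PDB file.

    Keeps heavy atoms of polymer (ATOM) residues only; for alternate
    locations the first-listed atom per name wins; insertion codes are
    rejected; only the first model of a multi-model file is used.
    """
    path = Path(path)
    if not path.exists():
        raise PdbFormatError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise PdbFormatError(f"{path}: no models")
    model = structure[0]
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        available = ", ".join(ch.name for ch in model) or "none"
        raise ChainNotFoundError(
            f"chain {chain_id!r} not in {path} (available: {available})"
        )
    residues = _parse_gemmi_chain(chain, path)
    if not residues:
        raise ChainNotFoundError(f"chain {chain_id!r} in {path} has no heavy atoms")
    return ChainStructure(chain_id, residues, source)


def read_only_chain(
    path: str | Path,
    rename: Optional[str] = None,
    source: StructureSource = StructureSource.EXPERIMENTAL,
) -> ChainStructure:
    """Read the single chain of a one-chain PDB file.

    ``rename`` overrides the chain id (useful when identity is carried by
    the file name rather than the one-character PDB chain column).
    """
    path = Path(path)
    if not path.exists():
        raise PdbFormatError(f"no such file: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise PdbFormatError(f"{path}: no models")
    model = structure[0]
    names = [ch.name for ch in model]
    if len(names) != 1:
        raise ChainNotFoundError(
            f"{path}: expected exactly one chain, found {names}"
        )
    residues = _parse_gemmi_chain(model[0], path)
    if not residues:
        raise ChainNotFoundError(f"{path}: chain has no heavy atoms")
    return ChainStructure(rename or names[0], residues, source)


def _parse_gemmi_chain(chain, path) -> List[ResidueRecord]:
    residues: List[ResidueRecord] = []
    for res in chain:
        if res.het_flag != "A" or res.is_water():
            continue
        if res.seqid.icode not in ("", " ", "\x00"):
            raise PdbFormatError(
                f"{path}: residue {res.seqid.num}{res.seqid.icode} has an "
                "insertion code; renumber to plain integers first"
            )
        atoms: Dict[str, np.ndarray] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.name in atoms:  # later altloc of an atom we already keep
                continue
            atoms[atom.name] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
            )
        if atoms:
            residues.append(ResidueRecord(res.seqid.num, res.name, atoms))
    return residues


def write_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write a chain as fixed-width ATOM records (single model).

    Chain ids longer than one character (the PDB column limit) are written
    as chain ``A``; dataset-level identity lives in the file name.
    """
    structure = gemmi.Structure()
    structure.name = "tmhc"
    model = gemmi.Model(1)
    gchain = gemmi.Chain(chain.chain_id if len(chain.chain_id) == 1 else "A")
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = res.resname
        gres.seqid = gemmi.SeqId(res.position, " ")
        gres.het_flag = "A"
        for name, coords in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*[float(c) for c in coords])
            atom.element = gemmi.Element(_element_for(name))
            atom.occ = 1.0
            atom.b_iso = 0.0
            gres.add_atom(atom)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_helix_annotation(path: str | Path) -> Dict[str, HelixAnnotation]:
    """Read a TM-helix annotation TSV (chain_id, helix_index, start, end).

    Returns one HelixAnnotation per chain; invariants are enforced.
    An empty table yields an empty mapping.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"chain_id", "helix_index", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    annotations: Dict[str, HelixAnnotation] = {}
    for chain_id, group in frame.groupby("chain_id", sort=True):
        group = group.sort_values("helix_index")
        segments = [(int(r.start), int(r.end)) for r in group.itertuples()]
        annotations[str(chain_id)] = HelixAnnotation(str(chain_id), segments)
    return annotations


def write_helix_annotation(
    annotations: Mapping[str, HelixAnnotation] | Iterable[HelixAnnotation],
    path: str | Path,
) -> None:
    if isinstance(annotations, Mapping):
        annotations = list(annotations.values())
    rows = [
        {"chain_id": a.chain_id, "helix_index": k, "start": s, "end": e}
        for a in annotations
        for k, (s, e) in enumerate(a.segments, start=1)
    ]
    pd.DataFrame(rows, columns=["chain_id", "helix_index", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_offset_table(path: str | Path) -> Dict[str, int]:
    """Read a TSV of per-chain integer position offsets (chain_id, offset)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    if not {"chain_id", "offset"} <= set(frame.columns):
        raise AnnotationError(f"{path}: expected columns chain_id, offset")
    return {str(r.chain_id): int(r.offset) for r in frame.itertuples()}


def apply_offset(chain: ChainStructure, offset: int) -> ChainStructure:
    """Shift every residue position by ``offset`` (sequence re-alignment)."""
    residues = [
        ResidueRecord(r.position + offset, r.resname, dict(r.atoms))
        for r in chain.residues
    ]
    return ChainStructure(chain.chain_id, residues, chain.source)
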