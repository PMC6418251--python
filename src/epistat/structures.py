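"""Crystal-structure models and charged-group geometry.

Parses PDB-format coordinate files into lightweight structure models and
measures the electrostatic-contact geometry of antigen-antibody interfaces:
representative-atom distances (Lys NZ, Arg CZ, Asp CG, Glu CD), minimum
distances between formally charged side-chain groups (ammonium/guanidinium
vs. carboxylate), interface salt-bridge detection, and terminal-excluded
C-alpha selections used by trajectory metrics.

Parsing and writing go through Biopython's ``Bio.PDB``; the containers here
are deliberately minimal (plain dataclasses keyed by author numbering) so
that geometry operations stay explicit and easy to audit.  Coordinates are
assumed already imaged/whole: no periodic minimum-image correction is applied.
HETATM records, waters and hydrogens are ignored by default — the geometry
analysis is heavy-atom only.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AtomLookupError,
    PDBParseError,
    ResidueLookupError,
    SelectionError,
    UsageError,
)

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "StructureModel",
    "ChargedGroupSpec",
    "ContactDefinition",
    "DEFAULT_CHARGED_GROUPS",
    "parse_pdb",
    "write_pdb",
    "representative_distance",
    "group_min_distance",
    "find_salt_bridges",
    "ca_mask",
    "contacts_to_frame",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """A single heavy atom: serial, name (e.g. ``NZ``), element, alt-loc, coords in A."""

    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass(frozen=True)
class ResidueKey:
    """Residue identity in author numbering: (chain, seq, insertion code, 3-letter name)."""

    chain_id: str
    res_seq: int
    i_code: str = ""
    res_name: str = ""

    def __str__(self) -> str:  # e.g. "I:LYS52"
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{self.i_code}"


@dataclass
class StructureModel:
    """One coordinate model: an ordered map from residues to their atoms."""

    model_index: int
    residues: dict[ResidueKey, list[AtomRecord]] = field(default_factory=dict)

    # -- iteration / indexing ------------------------------------------------

    def atoms(self) -> Iterator[tuple[ResidueKey, AtomRecord]]:
        for key, atom_list in self.residues.items():
            for atom in atom_list:
                yield key, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(v) for v in self.residues.values())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array in model order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.atoms()], dtype=float)

    def flat_index(self) -> dict[tuple[str, int, str, str], int]:
        """Map (chain, seq, icode, atom name) -> index into :meth:`coords` rows."""
        out: dict[tuple[str, int, str, str], int] = {}
        for i, (key, atom) in enumerate(self.atoms()):
            out[(key.chain_id, key.res_seq, key.i_code, atom.name)] = i
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[ResidueKey]:
        return [k for k in self.residues if k.chain_id == chain_id]

    # -- lookups -------------------------------------------------------------

    def find_residue(self, chain_id: str, res_seq: int, i_code: str = "") -> ResidueKey:
        for key in self.residues:
            if (key.chain_id, key.res_seq, key.i_code) == (chain_id, res_seq, i_code):
                return key
        raise ResidueLookupError(f"residue {chain_id}:{res_seq}{i_code} not in model")

    def resolve(self, key: ResidueKey) -> ResidueKey:
        """Return the model's own key matching ``key`` on (chain, seq, icode)."""
        if key in self.residues:
            return key
        return self.find_residue(key.chain_id, key.res_seq, key.i_code)

    def get_atom(self, key: ResidueKey, atom_name: str) -> AtomRecord:
        key = self.resolve(key)
        for atom in self.residues[key]:
            if atom.name == atom_name:
                return atom
        raise AtomLookupError(f"atom {atom_name!r} not found in residue {key}")

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with every atom moved to the given (n_atoms, 3) array."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise SelectionError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        new = StructureModel(self.model_index)
        i = 0
        for key, atom_list in self.residues.items():
            new.residues[key] = [
                AtomRecord(a.serial, a.name, a.element, a.alt_loc, coords[i + j])
                for j, a in enumerate(atom_list)
            ]
            i += len(atom_list)
        return new


@dataclass(frozen=True)
class ChargedGroup:
    polarity: str              # "basic" | "acidic"
    representative_atom: str   # e.g. NZ
    group_atoms: frozenset[str]


ChargedGroupSpec = dict[str, ChargedGroup]

#: Side-chain charged-group conventions: Lys ammonium (NZ), Arg guanidinium
#: (NE/NH1/NH2, representative CZ), Asp carboxylate (OD1/OD2, representative CG),
#: Glu carboxylate (OE1/OE2, representative CD).
DEFAULT_CHARGED_GROUPS: ChargedGroupSpec = {
    "LYS": ChargedGroup("basic", "NZ", frozenset({"NZ"})),
    "ARG": ChargedGroup("basic", "CZ", frozenset({"NE", "NH1", "NH2"})),
    "ASP": ChargedGroup("acidic", "CG", frozenset({"OD1", "OD2"})),
    "GLU": ChargedGroup("acidic", "CD", frozenset({"OE1", "OE2"})),
}


@dataclass
class ContactDefinition:
    """A named charged-residue pair with its measurement atoms and distance threshold (A)."""

    label: str
    res_a: ResidueKey
    res_b: ResidueKey
    atom_a: str
    atom_b: str
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("contact threshold must be positive")


# --------------------------------------------------------------------------
# PDB I/O (via Bio.PDB)
# --------------------------------------------------------------------------

def _as_handle(source) -> io.StringIO | object:
    if isinstance(source, Path):
        return open(source)
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "MODEL")):
            return io.StringIO(source)
        return open(source)
    return source  # already a file-like object


def parse_pdb(source, *, include_het: bool = False, keep_hydrogens: bool = False
              ) -> list[StructureModel]:
    """Parse PDB-format text into one :class:`StructureModel` per MODEL block.

    ``source`` may be a path, raw PDB text, or an open handle.  Alternate
    locations are resolved to the highest-occupancy conformer (ties keep the
    first encountered); HETATM records and hydrogens are dropped unless
    requested.  Raises :class:`PDBParseError` on empty or malformed input,
    naming the offending line where Biopython reports one.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    handle = _as_handle(source)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", handle)
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB input: {exc}") from exc
    finally:
        if handle is not source and hasattr(handle, "close"):
            handle.close()

    models: list[StructureModel] = []
    for bio_model in structure:
        model = StructureModel(model_index=bio_model.serial_num or len(models) + 1)
        for chain in bio_model:
            for residue in chain:
                het_flag, res_seq, i_code = residue.id
                if het_flag.strip() and not include_het:
                    continue
                key = ResidueKey(
                    chain_id=chain.id,
                    res_seq=res_seq,
                    i_code=i_code.strip(),
                    res_name=residue.get_resname().strip(),
                )
                atoms: dict[str, AtomRecord] = {}
                for atom in residue.get_unpacked_list():
                    element = (atom.element or "").strip().upper()
                    if element in {"H", "D"} and not keep_hydrogens:
                        continue
                    rec = AtomRecord(
                        serial=atom.serial_number or 0,
                        name=atom.get_name().strip(),
                        element=element,
                        alt_loc=atom.get_altloc().strip(),
                        coords=np.array(atom.get_coord(), dtype=float),
                    )
                    prev = atoms.get(rec.name)
                    if prev is None:
                        atoms[rec.name] = rec
                        atoms[rec.name]._occ = atom.get_occupancy() or 1.0  # type: ignore[attr-defined]
                    else:
                        occ = atom.get_occupancy() or 1.0
                        if occ > getattr(prev, "_occ", 1.0):  # strict: ties keep first
                            atoms[rec.name] = rec
                            atoms[rec.name]._occ = occ  # type: ignore[attr-defined]
                if atoms:
                    model.residues[key] = list(atoms.values())
        if model.n_atoms:
            models.append(model)

    if not models:
        raise PDBParseError("no ATOM records found in input")
    return models


def write_pdb(models: StructureModel | Sequence[StructureModel], target=None) -> str:
    """Write models as PDB-format text (multi-model when several are given).

    Returns the text; if ``target`` is a path or handle it is also written there.
    """
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    if isinstance(models, StructureModel):
        models = [models]

    builder = StructureBuilder()
    builder.init_structure("S")
    for i, model in enumerate(models):
        builder.init_model(i, i)
        current_chain = None
        serial = 1
        for key, atom_list in model.residues.items():
            if key.chain_id != current_chain:
                builder.init_chain(key.chain_id)
                builder.init_seg("    ")
                current_chain = key.chain_id
            builder.init_residue(key.res_name or "UNK", " ", key.res_seq, key.i_code or " ")
            for atom in atom_list:
                fullname = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                builder.init_atom(
                    atom.name, atom.coords.astype(np.float64), 0.0, 1.0,
                    " ", fullname, serial, atom.element or None,
                )
                serial += 1

    pdb_io = PDBIO()
    pdb_io.set_structure(builder.get_structure())
    buf = io.StringIO()
    pdb_io.save(buf)
    text = buf.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text)
        else:
            target.write(text)
    return text


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _group_for(model: StructureModel, key: ResidueKey, spec: ChargedGroupSpec) -> ChargedGroup:
    key = model.resolve(key)
    try:
        return spec[key.res_name]
    except KeyError:
        raise UsageError(f"residue {key} ({key.res_name}) is not a charged residue type")


def representative_distance(model: StructureModel, res_a: ResidueKey, res_b: ResidueKey,
                            spec: ChargedGroupSpec = DEFAULT_CHARGED_GROUPS) -> float:
    """Distance (A) between the two residues' representative side-chain atoms."""
    grp_a = _group_for(model, res_a, spec)
    grp_b = _group_for(model, res_b, spec)
    atom_a = model.get_atom(res_a, grp_a.representative_atom)
    atom_b = model.get_atom(res_b, grp_b.representative_atom)
    return float(np.linalg.norm(atom_a.coords - atom_b.coords))


def group_min_distance(model: StructureModel, res_a: ResidueKey, res_b: ResidueKey,
                       spec: ChargedGroupSpec = DEFAULT_CHARGED_GROUPS) -> float:
    """Minimum distance (A) between the basic group atoms and the acidic group atoms.

    One residue must be basic (Lys/Arg) and the other acidic (Asp/Glu).
    """
    grp_a = _group_for(model, res_a, spec)
    grp_b = _group_for(model, res_b, spec)
    if grp_a.polarity == grp_b.polarity:
        raise UsageError(
            f"group_min_distance needs one basic and one acidic residue, got "
            f"{grp_a.polarity} ({model.resolve(res_a)}) and {grp_b.polarity} "
            f"({model.resolve(res_b)})"
        )
    coords_a = np.array([model.get_atom(res_a, n).coords for n in sorted(grp_a.group_atoms)])
    coords_b = np.array([model.get_atom(res_b, n).coords for n in sorted(grp_b.group_atoms)])
    diffs = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(axis=-1)).min())


def find_salt_bridges(model: StructureModel, chains_a: Iterable[str], chains_b: Iterable[str],
                      spec: ChargedGroupSpec = DEFAULT_CHARGED_GROUPS,
                      cutoff: float = 4.5) -> list[ContactDefinition]:
    """All inter-selection (basic, acidic) pairs with group-minimum distance <= cutoff.

    Pairs take one residue from each chain set (the sets must be disjoint and
    non-empty); results are sorted by group-minimum distance.  Each contact's
    ``threshold`` records the measured representative-atom distance, the
    convention used for downstream trajectory occupancy thresholds.
    """
    chains_a, chains_b = set(chains_a), set(chains_b)
    if not chains_a or not chains_b:
        raise UsageError("both chain selections must be non-empty")
    if chains_a & chains_b:
        raise UsageError(f"chain selections overlap: {sorted(chains_a & chains_b)}")
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")

    def charged_in(chains: set[str]) -> list[ResidueKey]:
        return [k for k in model.residues if k.chain_id in chains and k.res_name in spec]

    found: list[tuple[float, ContactDefinition]] = []
    for ka in charged_in(chains_a):
        for kb in charged_in(chains_b):
            grp_a, grp_b = spec[ka.res_name], spec[kb.res_name]
            if grp_a.polarity == grp_b.polarity:
                continue
            try:
                dmin = group_min_distance(model, ka, kb, spec)
            except AtomLookupError:
                continue  # truncated side chain: skip rather than guess
            if dmin <= cutoff:
                rep = representative_distance(model, ka, kb, spec)
                found.append((dmin, ContactDefinition(
                    label=f"{ka}-{kb}",
                    res_a=ka, res_b=kb,
                    atom_a=grp_a.representative_atom,
                    atom_b=grp_b.representative_atom,
                    threshold=rep,
                )))
    found.sort(key=lambda t: t[0])
    return [c for _, c in found]


def ca_mask(model: StructureModel, chains: Iterable[str], terminal_exclude: int = 5
            ) -> np.ndarray:
    """Flat-coordinate indices of C-alpha atoms, chain by chain, with the first and
    last ``terminal_exclude`` residues of each selected chain removed.

    Terminal residues of MD constructs are floppy and inflate RMSDs, hence the
    default exclusion of five per terminus.
    """
    if terminal_exclude < 0:
        raise UsageError("terminal_exclude must be >= 0")
    chains = list(dict.fromkeys(chains))
    if not chains:
        raise SelectionError("empty chain selection")
    index = model.flat_index()
    out: list[int] = []
    for chain_id in chains:
        res_keys = [k for k in model.chain_residues(chain_id)
                    if any(a.name == "CA" for a in model.residues[k])]
        if not res_keys:
            raise SelectionError(f"chain {chain_id!r} has no C-alpha atoms")
        if len(res_keys) < 2 * terminal_exclude + 1:
            raise SelectionError(
                f"chain {chain_id!r} has {len(res_keys)} residues, too short to "
                f"exclude {terminal_exclude} per terminus"
            )
        kept = res_keys[terminal_exclude: len(res_keys) - terminal_exclude or None]
        out.extend(index[(k.chain_id, k.res_seq, k.i_code, "CA")] for k in kept)
    return np.asarray(out, dtype=int)


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def contacts_to_frame(model: StructureModel, contacts: Sequence[ContactDefinition],
                      spec: ChargedGroupSpec = DEFAULT_CHARGED_GROUPS) -> pd.DataFrame:
    """Contact table with one row per (contact, convention).

    Both distance conventions are reported for every contact — representative
    atoms and group minimum — and each row records which convention produced it.
    """
    rows = []
    for c in contacts:
        ka, kb = model.resolve(c.res_a), model.resolve(c.res_b)
        rep = representative_distance(model, ka, kb, spec)
        gmin = group_min_distance(model, ka, kb, spec)
        base = dict(label=c.label, chain_a=ka.chain_id, res_a=f"{ka.res_name}{ka.res_seq}",
                    chain_b=kb.chain_id, res_b=f"{kb.res_name}{kb.res_seq}")
        rows.append({**base, "convention": "representative", "distance_A": round(rep, 3)})
        rows.append({**base, "convention": "group_min", "distance_A": round(gmin, 3)})
    return pd.DataFrame(rows, columns=["label", "chain_a", "res_a", "chain_b", "res_b",
                                       "convention", "distance_A"])
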