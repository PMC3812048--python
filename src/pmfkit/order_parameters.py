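"""Order parameters over structure coordinates.

Four collective variables drive the gating analysis: two center-of-mass
gate distances (the ~20 A "thick" gate between TM1 and TM8 residue
groups, and the extracellular thin gate), a z-displacement of a mobile
species relative to its binding site, and a minimum-contact diagnostic
used to rule out stray-ion contamination of apo windows.

Atom selection defaults to all heavy (non-hydrogen) atoms of the named
residues; ``backbone`` / ``ca`` switches narrow that. PDB ingestion uses
Biopython; each MODEL becomes one frame; for altloc duplicates the
highest-occupancy conformer wins (ties resolved alphabetically).
"""
from __future__ import annotations

import fnmatch
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser

__all__ = [
    "FrameCoordinates", "Selection", "CollectiveVariableSpec",
    "SelectionError", "EmptyStructureError", "read_structure", "com",
    "gate_distance", "z_displacement", "min_contact_distance",
    "THICK_GATE", "EC_THIN_GATE", "NA2_SITE_RESIDUES", "S1_SITE_RESIDUES",
    "write_cv_series",
]

#: Na2-site residue numbers: TM1 (Ala38, Ile41) vs TM8 (Ala309, Ser312, Thr313).
NA2_TM1 = (38, 41)
NA2_TM8 = (309, 312, 313)
NA2_SITE_RESIDUES = NA2_TM1 + NA2_TM8
#: Extracellular thin gate: mobile TM9/TM10 loop vs stationary TM1 residues.
EC_MOBILE = (360, 361, 362)
EC_STATIONARY = (47, 48, 49)
#: Substrate S1 site residues used as the z reference for the substrate CV.
S1_SITE_RESIDUES = (117, 121, 220, 318)

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class SelectionError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


@dataclass
class FrameCoordinates:
    """One frame of atomic coordinates with identities and masses."""

    chain: np.ndarray      # str per atom
    resseq: np.ndarray     # int author residue number
    icode: np.ndarray      # insertion code, '' if none
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    mass: np.ndarray       # amu
    coords: np.ndarray     # (n, 3) Angstrom
    frame_id: int = 0

    def __post_init__(self):
        n = len(self.coords)
        if n == 0:
            raise EmptyStructureError("frame holds no atoms")
        if np.any(self.mass <= 0):
            bad = int(np.argmax(self.mass <= 0))
            raise ValueError(f"non-positive mass for atom {self.atom_name[bad]} "
                             f"({self.element[bad]}) in residue "
                             f"{self.resname[bad]} {self.resseq[bad]}")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "FrameCoordinates":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return FrameCoordinates(self.chain, self.resseq, self.icode, self.resname,
                                self.atom_name, self.element, self.mass, xyz,
                                self.frame_id)


@dataclass(frozen=True)
class Selection:
    """Atom selection: conjunction of chain / residue / name / element filters.

    ``from_string`` parses a mini-language of whitespace-separated clauses:
    ``chain A``, ``resi 38,41`` (or ranges ``38-41``), ``resn ALA``,
    ``name CA`` (glob allowed, e.g. ``name C*``), ``heavy``, ``backbone``,
    ``ca``, ``all``.
    """

    chain: Optional[str] = None
    resseq: Optional[Tuple[int, ...]] = None
    resname: Optional[Tuple[str, ...]] = None
    name_glob: Optional[str] = None
    mode: str = "heavy"   # heavy | backbone | ca | all

    _MODES = ("heavy", "backbone", "ca", "all")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise SelectionError(f"unknown selection mode {self.mode!r}")

    @classmethod
    def from_string(cls, expr: str) -> "Selection":
        tokens = expr.split()
        kw = {}
        i = 0
        while i < len(tokens):
            t = tokens[i].lower()
            if t in ("heavy", "backbone", "ca", "all"):
                kw["mode"] = t
                i += 1
            elif t in ("chain", "resi", "resn", "name"):
                if i + 1 >= len(tokens):
                    raise SelectionError(f"clause {t!r} needs a value in {expr!r}")
                val = tokens[i + 1]
                if t == "chain":
                    kw["chain"] = val
                elif t == "resi":
                    nums: List[int] = []
                    for part in val.split(","):
                        if "-" in part[1:]:
                            a, b = part.split("-", 1)
                            nums.extend(range(int(a), int(b) + 1))
                        else:
                            nums.append(int(part))
                    kw["resseq"] = tuple(nums)
                elif t == "resn":
                    kw["resname"] = tuple(v.upper() for v in val.split(","))
                else:
                    kw["name_glob"] = val
                i += 2
            else:
                raise SelectionError(f"cannot parse token {tokens[i]!r} in {expr!r}")
        return cls(**kw)

    def describe(self) -> str:
        parts = []
        if self.chain:
            parts.append(f"chain {self.chain}")
        if self.resseq:
            parts.append("resi " + ",".join(map(str, self.resseq)))
        if self.resname:
            parts.append("resn " + ",".join(self.resname))
        if self.name_glob:
            parts.append(f"name {self.name_glob}")
        parts.append(self.mode)
        return " ".join(parts)

    def resolve(self, frame: FrameCoordinates) -> np.ndarray:
        mask = np.ones(len(frame), dtype=bool)
        if self.chain is not None:
            mask &= frame.chain == self.chain
        if self.resseq is not None:
            mask &= np.isin(frame.resseq, self.resseq)
        if self.resname is not None:
            mask &= np.isin(frame.resname, self.resname)
        if self.name_glob is not None:
            names = frame.atom_name
            mask &= np.array([fnmatch.fnmatchcase(n, self.name_glob) for n in names])
        if self.mode == "heavy":
            mask &= frame.element != "H"
        elif self.mode == "backbone":
            mask &= np.isin(frame.atom_name, list(_BACKBONE_NAMES))
            mask &= frame.element != "H"
        elif self.mode == "ca":
            mask &= frame.atom_name == "CA"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection resolves to no atoms: {self.describe()!r}")
        return idx


@dataclass(frozen=True)
class CollectiveVariableSpec:
    """Declarative CV: a named pairing of two selections and a kind."""

    name: str
    kind: str  # com_distance | z_displacement | min_contact
    selection_a: Selection
    selection_b: Selection

    _KINDS = ("com_distance", "z_displacement", "min_contact")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")

    def evaluate(self, frame: FrameCoordinates) -> float:
        if self.kind == "com_distance":
            return gate_distance(frame, self)
        if self.kind == "z_displacement":
            return z_displacement(frame, self.selection_a, self.selection_b)
        return min_contact_distance(frame, self.selection_a, self.selection_b)


def _resi_selection(nums, chain=None, mode="heavy") -> Selection:
    return Selection(chain=chain, resseq=tuple(nums), mode=mode)


#: Thick-gate CV: COM(TM1 Ala38+Ile41) to COM(TM8 Ala309+Ser312+Thr313).
THICK_GATE = CollectiveVariableSpec(
    "thick_gate", "com_distance",
    _resi_selection(NA2_TM1), _resi_selection(NA2_TM8))

#: EC thin-gate CV: mobile loop (360-362) to stationary TM1 (47-49).
EC_THIN_GATE = CollectiveVariableSpec(
    "ec_thin_gate", "com_distance",
    _resi_selection(EC_MOBILE), _resi_selection(EC_STATIONARY))


# ---------------------------------------------------------------------------
# PDB ingestion
# ---------------------------------------------------------------------------

def _atom_mass(element: str, atom_name: str, resname: str, resseq) -> float:
    el = element.capitalize() if element else ""
    if el not in atom_weights:
        raise ValueError(f"unknown element {element!r} for atom {atom_name!r} "
                         f"in residue {resname} {resseq}")
    return float(atom_weights[el])


def _pick_altloc(children):
    """Highest occupancy wins; ties go to the alphabetically first altloc."""
    def key(atom):
        occ = atom.get_occupancy()
        return (-(occ if occ is not None else 0.0), atom.get_altloc())
    return sorted(children, key=key)[0]


def read_structure(pdb_source: Union[str, Path, io.StringIO],
                   first_model_only: bool = False) -> List[FrameCoordinates]:
    """Parse PDB text into one FrameCoordinates per MODEL.

    ``pdb_source`` may be a path, raw PDB text, or a text handle. ATOM and
    HETATM records are both retained.
    """
    if isinstance(pdb_source, io.IOBase) or hasattr(pdb_source, "read"):
        handle = pdb_source
    else:
        text_or_path = str(pdb_source)
        if "\n" in text_or_path or text_or_path.lstrip().startswith(("ATOM", "HETATM", "MODEL", "HEADER", "CRYST", "REMARK")):
            handle = io.StringIO(text_or_path)
        else:
            handle = open(text_or_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", handle)
    frames = []
    for model in structure:
        chains, resseqs, icodes, resnames, names, elements, masses, xyz = \
            [], [], [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                het, seq, icode = residue.get_id()
                for atom in residue:
                    if atom.is_disordered():
                        atom = _pick_altloc(atom.disordered_get_list())
                    chains.append(chain.id)
                    resseqs.append(seq)
                    icodes.append(icode.strip())
                    resnames.append(residue.get_resname().strip())
                    names.append(atom.get_name())
                    el = (atom.element or "").strip().upper()
                    if not el:
                        el = _infer_element(atom.get_name())
                    elements.append(el)
                    masses.append(_atom_mass(el, atom.get_name(),
                                             residue.get_resname(), seq))
                    xyz.append(atom.get_coord())
        if not xyz:
            continue
        frames.append(FrameCoordinates(
            np.array(chains), np.array(resseqs, dtype=int), np.array(icodes),
            np.array(resnames), np.array(names), np.array(elements),
            np.array(masses, dtype=float), np.array(xyz, dtype=float),
            frame_id=model.id))
        if first_model_only:
            break
    if not frames:
        raise EmptyStructureError("no ATOM/HETATM records found")
    return frames


def _infer_element(atom_name: str) -> str:
    """PDB-convention element inference from the atom name."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():           # e.g. 1HB2
        name = name.lstrip("0123456789")
    # two-letter symbols only for elements that cannot be confused with
    # remoteness-labelled protein atom names (CA is a calcium only in a
    # properly aligned PDB element column, which is handled upstream)
    if name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "MN", "SE"):
        return name[:2].upper()
    return name[0].upper()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def com(frame: FrameCoordinates, selection: Selection) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (3-vector, A)."""
    idx = selection.resolve(frame)
    m = frame.mass[idx]
    return (m[:, None] * frame.coords[idx]).sum(axis=0) / m.sum()


def gate_distance(frame: FrameCoordinates,
                  spec: CollectiveVariableSpec) -> float:
    """Euclidean distance between the COMs of the spec's two selections."""
    a = com(frame, spec.selection_a)
    b = com(frame, spec.selection_b)
    return float(np.linalg.norm(a - b))


def z_displacement(frame: FrameCoordinates, mobile: Selection,
                   site: Selection) -> float:
    """z(COM(mobile)) - z(COM(site)); ~0 when bound, +toward extracellular."""
    return float(com(frame, mobile)[2] - com(frame, site)[2])


def min_contact_distance(frame: FrameCoordinates, probe: Selection,
                         site: Selection) -> float:
    """Minimum over all probe-site atom pairs of the Euclidean distance."""
    pi = probe.resolve(frame)
    si = site.resolve(frame)
    d = np.linalg.norm(frame.coords[pi][:, None, :] - frame.coords[si][None, :, :],
                       axis=-1)
    return float(d.min())


def write_cv_series(path: Union[str, Path],
                    rows: Sequence[Tuple[int, str, float]]) -> None:
    """Columnar text time series: frame cv_name value."""
    with open(path, "w") as fh:
        fh.write("# frame cv_name value\n")
        for frame_id, name, value in rows:
            fh.write(f"{frame_id} {name} {value!r}\n")
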