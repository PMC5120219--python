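"""Readers and writers for the formats the rest of the package consumes.

Coordinates come in as PDB files (single- or multi-model, the multi-model
dialect doubling as the trajectory interchange format), sequences as FASTA,
and force/extension traces as tab-separated text with ``#``-prefixed
metadata lines.  PDB parsing and writing stand on :mod:`gemmi`; FASTA on
:mod:`Bio.SeqIO`.  The in-memory containers defined here (:class:`Structure`,
:class:`Trajectory`, :class:`ForceTrace`) are deliberately small and
numpy-friendly: every downstream module works on them, never on raw files.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "Structure",
    "DomainDefinition",
    "Trajectory",
    "ForceTrace",
    "ATOMIC_MASSES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_fasta",
    "write_fasta",
    "read_force_trace",
    "write_force_trace",
]


class ParseError(ValueError):
    """A file violated the format contract (message names the offence)."""


#: Element -> standard atomic mass in Da.  Deliberately a packaged table:
#: an element missing here is an error, never a silent zero mass.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}


def element_mass(element: str) -> float:
    """Mass in Da for an element symbol; unknown symbols raise."""
    try:
        return ATOMIC_MASSES[element.strip().upper()]
    except KeyError:
        raise ParseError(f"unknown element {element!r}: no mass available") from None


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    altloc: str
    occupancy: float
    coordinates: tuple[float, float, float]
    mass: float
    hetero: bool = False


@dataclass
class Structure:
    """A set of atoms from one coordinate model.

    Residue numbering is taken verbatim from the file (the deposited
    structures use processed-protein numbering); no renumbering happens
    anywhere in the package.
    """

    atoms: list[Atom]
    model_id: int = 1

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.coordinates):
                raise ParseError(f"non-finite coordinates for atom serial {a.serial}")
            if not 0.0 <= a.occupancy <= 1.0:
                raise ParseError(f"occupancy {a.occupancy} outside [0,1] for atom serial {a.serial}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def select(
        self,
        chain: str | None = None,
        residues: tuple[int, int] | None = None,
        name: str | None = None,
        element: str | None = None,
        hetero: bool | None = None,
    ) -> "Structure":
        """Subset by chain, inclusive residue range, atom name or element."""
        kept = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if residues is not None and not residues[0] <= a.residue_number <= residues[1]:
                continue
            if name is not None and a.name != name:
                continue
            if element is not None and a.element.upper() != element.upper():
                continue
            if hetero is not None and a.hetero != hetero:
                continue
            kept.append(a)
        return Structure(atoms=kept, model_id=self.model_id)

    def residue_numbers(self, chain: str | None = None) -> list[int]:
        """Sorted distinct residue numbers of non-hetero residues."""
        seen = {
            a.residue_number
            for a in self.atoms
            if not a.hetero and (chain is None or a.chain == chain)
        }
        return sorted(seen)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def translated(self, shift: Sequence[float]) -> "Structure":
        s = np.asarray(shift, dtype=float)
        return self.transformed(np.eye(3), s)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "Structure":
        """Return a copy with coordinates ``R @ x + t`` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            x = R @ np.asarray(a.coordinates) + t
            new_atoms.append(replace(a, coordinates=(float(x[0]), float(x[1]), float(x[2]))))
        return Structure(atoms=new_atoms, model_id=self.model_id)


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive residue range naming one EC repeat (or any domain)."""

    name: str
    chain: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"domain {self.name}: first_residue {self.first_residue} > last_residue {self.last_residue}"
            )

    def contains(self, chain: str, residue_number: int) -> bool:
        return chain == self.chain and self.first_residue <= residue_number <= self.last_residue


def check_domains_disjoint(domains: Iterable[DomainDefinition]) -> None:
    """Raise if two domains on the same chain overlap."""
    by_chain: dict[str, list[DomainDefinition]] = {}
    for d in domains:
        by_chain.setdefault(d.chain, []).append(d)
    for chain, ds in by_chain.items():
        ds = sorted(ds, key=lambda d: d.first_residue)
        for a, b in zip(ds, ds[1:]):
            if b.first_residue <= a.last_residue:
                raise ValueError(f"domains {a.name} and {b.name} overlap on chain {chain}")


@dataclass
class Trajectory:
    """Ordered coordinate frames with strictly increasing times (ns)."""

    frames: list[Structure]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times differ in length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        inv = None
        for i, f in enumerate(self.frames):
            key = [(a.chain, a.residue_number, a.name) for a in f.atoms]
            if inv is None:
                inv = key
            elif key != inv:
                raise ValueError(f"frame {i} has a different atom inventory from frame 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ForceTrace:
    """A pulling record: time (ns), end-to-end extension (nm), force (pN)."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    mode: str = "constant-velocity"
    speed: float | None = None            # nm/ns, constant-velocity only
    spring_constant: float | None = None  # kcal mol^-1 Å^-2
    applied_force: float | None = None    # pN, constant-force only

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time, extension and force must have equal length")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ParseError("time column is not strictly increasing")
        if self.mode not in ("constant-velocity", "constant-force"):
            raise ValueError(f"unknown pulling mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _structure_from_gemmi_model(model: gemmi.Model, model_id: int) -> Structure:
    # altloc policy: keep highest occupancy, first record on tie
    best: dict[tuple[str, int, str], Atom] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                el = atom.element.name.upper()
                if not el or el == "X":
                    raise ParseError(
                        f"atom {atom.name!r} in residue {residue.name} {residue.seqid.num}: "
                        "element could not be determined"
                    )
                key = (chain.name, residue.seqid.num, atom.name)
                rec = Atom(
                    serial=atom.serial,
                    name=atom.name,
                    element=el,
                    residue_name=residue.name.strip(),
                    residue_number=residue.seqid.num,
                    chain=chain.name,
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    occupancy=float(atom.occ),
                    coordinates=(atom.pos.x, atom.pos.y, atom.pos.z),
                    mass=element_mass(el),
                    hetero=het,
                )
                if key not in best:
                    best[key] = rec
                    order.append(key)
                elif rec.occupancy > best[key].occupancy:
                    best[key] = rec
    atoms = [best[k] for k in order]
    if not atoms:
        raise ParseError(f"model {model_id} contains no atoms")
    return Structure(atoms=atoms, model_id=model_id)


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate field {fieldtxt!r} on line {lineno}"
                    ) from None
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    return st


def read_structure(path: str | Path, model: int | str = 1) -> Structure | list[Structure]:
    """Read a PDB file into one :class:`Structure` or (``model='all'``) a list.

    Altlocs are resolved to the highest-occupancy record (first wins a tie);
    HETATM records — including the calcium ions, whose element column
    distinguishes them from carbon — are retained with ``hetero=True``.
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if model == "all":
        return [_structure_from_gemmi_model(m, i + 1) for i, m in enumerate(st)]
    if not isinstance(model, int):
        raise ValueError("model must be an int or 'all'")
    if not 1 <= model <= len(st):
        raise ParseError(f"{path}: model {model} not present (file has {len(st)})")
    return _structure_from_gemmi_model(st[model - 1], model)


def _gemmi_from_structures(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "cadmech"
    for i, s in enumerate(structures):
        # gemmi add_* methods copy their argument, so build bottom-up:
        # group atoms, finish each residue, then assemble chains and model
        grouped: dict[str, list[tuple[tuple[int, str, bool], list[Atom]]]] = {}
        for a in s.atoms:
            runs = grouped.setdefault(a.chain, [])
            rkey = (a.residue_number, a.residue_name, a.hetero)
            if not runs or runs[-1][0] != rkey:
                runs.append((rkey, []))
            runs[-1][1].append(a)
        model = gemmi.Model(i + 1)
        for chain_name, runs in grouped.items():
            chain = gemmi.Chain(chain_name)
            for (resnum, resname, hetero), atoms in runs:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "H" if hetero else "A"
                for a in atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element.capitalize())
                    ga.pos = gemmi.Position(*a.coordinates)
                    ga.occ = a.occupancy
                    ga.serial = a.serial
                    if a.altloc:
                        ga.altloc = a.altloc
                    res.add_atom(ga)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    _gemmi_from_structures([structure]).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB; frame times (ns) go into REMARK 100 lines."""
    st = _gemmi_from_structures(traj.frames)
    text = st.make_pdb_string()
    out_lines: list[str] = []
    frame = 0
    for line in text.splitlines():
        out_lines.append(line)
        if line.startswith("MODEL"):
            out_lines.append(f"REMARK 100 TIME_NS {traj.times[frame]:.9g}")
            frame += 1
    Path(path).write_text("\n".join(out_lines) + "\n")


def read_trajectory(path: str | Path, dt: float | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frame times are taken from ``REMARK 100 TIME_NS`` lines when present,
    otherwise from ``dt`` (ns between frames, first frame at 0).
    """
    times: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 100 TIME_NS"):
            times.append(float(line.split()[-1]))
    frames = read_structure(path, model="all")
    if not isinstance(frames, list):
        frames = [frames]
    if len(times) != len(frames):
        if dt is None:
            raise ParseError(
                f"{path}: no per-frame TIME_NS remarks found and no dt supplied"
            )
        times = [dt * i for i in range(len(frames))]
    return Trajectory(frames=frames, times=np.asarray(times))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Force traces
# ---------------------------------------------------------------------------

_META_KEYS = {
    "mode": ("mode", str),
    "speed_nm_per_ns": ("speed", float),
    "ks_kcal_mol_A2": ("spring_constant", float),
    "force_pN": ("applied_force", float),
}

_REQUIRED_COLUMNS = ("time_ns", "extension_nm", "force_pN")


def read_force_trace(path: str | Path) -> ForceTrace:
    """Read a tab-separated force trace.

    The file must have a header naming ``time_ns``, ``extension_nm`` and
    ``force_pN`` columns; pulling metadata lives in ``#``-prefixed lines of
    the form ``# key: value`` (keys: mode, speed_nm_per_ns, ks_kcal_mol_A2,
    force_pN).
    """
    meta: dict[str, object] = {}
    data_lines: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip()[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip()
                if key in _META_KEYS:
                    attr, conv = _META_KEYS[key]
                    meta[attr] = conv(value.strip())
            continue
        data_lines.append(line)
    if not data_lines:
        raise ParseError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep="\t", float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return ForceTrace(
        time=df["time_ns"].to_numpy(float),
        extension=df["extension_nm"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        **meta,  # type: ignore[arg-type]
    )


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace in the dialect :func:`read_force_trace` reads.

    Round-trips bit-identically: values are written with :func:`repr`
    precision.
    """
    lines = [f"# mode: {trace.mode}"]
    if trace.speed is not None:
        lines.append(f"# speed_nm_per_ns: {trace.speed!r}")
    if trace.spring_constant is not None:
        lines.append(f"# ks_kcal_mol_A2: {trace.spring_constant!r}")
    if trace.applied_force is not None:
        lines.append(f"# force_pN: {trace.applied_force!r}")
    lines.append("\t".join(_REQUIRED_COLUMNS))
    for t, x, f in zip(trace.time, trace.extension, trace.force):
        lines.append(f"{float(t)!r}\t{float(x)!r}\t{float(f)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
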