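"""PDB structures, multi-model trajectories, and named residue-range regions.

The trajectory container is deliberately minimal: an ordered list of
topologically identical frames plus strictly increasing times in
nanoseconds. Region selections follow PDB author numbering with 1-based
inclusive ranges, which is how SH2-domain boundaries are quoted in the
literature (N-SH2 1-103, C-SH2 111-213, PTP 253-529, the exon-6 region
215-252, and the functional loops of N-SH2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .elements import element_from_atom_name, vdw_radius

#: Recording interval of the analyzed conformer stream, ns per frame.
DEFAULT_FRAME_INTERVAL_NS = 0.005


class PDBParseError(ValueError):
    """Raised for malformed PDB records; message carries the line number."""


class TopologyError(ValueError):
    """Raised when frames of a multi-model file disagree on atom identity."""


class SelectionError(KeyError):
    """Raised for unknown region names or empty selections."""


AtomIdentity = tuple[str, int, str]  # (chain, residue_number, atom name)


@dataclass(frozen=True)
class Atom:
    """One atom of a structure, PDB author numbering.

    ``bfactor`` doubles as the annotation channel (interface distances,
    per-residue RMSD) when structures are exported for rendering.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    vdw_radius: float
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.strip().upper() != "H"

    @property
    def identity(self) -> AtomIdentity:
        return (self.chain, self.residue_number, self.name)


class Structure:
    """An ordered collection of atoms representing one conformer."""

    def __init__(self, atoms: Sequence[Atom], label: str = "") -> None:
        if not atoms:
            raise ValueError("a Structure must contain at least one atom")
        self.atoms: list[Atom] = list(atoms)
        self.label = label
        seen: set[AtomIdentity] = set()
        for a in self.atoms:
            if a.identity in seen:
                raise ValueError(f"duplicate atom identity {a.identity}")
            seen.add(a.identity)
        self._index: dict[AtomIdentity, int] = {
            a.identity: i for i, a in enumerate(self.atoms)
        }

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstroms."""
        return np.array([a.position for a in self.atoms])

    @property
    def identities(self) -> list[AtomIdentity]:
        return [a.identity for a in self.atoms]

    def atom(self, chain: str, residue_number: int, name: str) -> Atom:
        try:
            return self.atoms[self._index[(chain, residue_number, name)]]
        except KeyError:
            raise SelectionError(
                f"no atom ({chain!r}, {residue_number}, {name!r}) in {self.label!r}"
            ) from None

    def index_of(self, identity: AtomIdentity) -> int:
        try:
            return self._index[identity]
        except KeyError:
            raise SelectionError(f"no atom {identity} in {self.label!r}") from None

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """New structure, same identities, replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms, label if label is not None else self.label)

    def with_bfactors(self, bfactors: Sequence[float]) -> "Structure":
        if len(bfactors) != len(self.atoms):
            raise ValueError("bfactor array length mismatch")
        atoms = [replace(a, bfactor=float(b)) for a, b in zip(self.atoms, bfactors)]
        return Structure(atoms, self.label)

    def subset(self, indices: Sequence[int], label: str | None = None) -> "Structure":
        if len(indices) == 0:
            raise SelectionError("empty selection")
        return Structure(
            [self.atoms[i] for i in indices],
            label if label is not None else self.label,
        )

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_number) pairs."""
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain, a.residue_number)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


class Trajectory:
    """Ordered, topologically identical frames with times in ns."""

    def __init__(
        self, frames: Sequence[Structure], times: Sequence[float] | None = None
    ) -> None:
        if not frames:
            raise ValueError("a Trajectory needs at least one frame")
        ref = frames[0].identities
        for k, fr in enumerate(frames[1:], start=2):
            if fr.identities != ref:
                raise TopologyError(
                    f"frame {k} atom identity list differs from frame 1"
                )
        if times is None:
            times = [i * DEFAULT_FRAME_INTERVAL_NS for i in range(len(frames))]
        times_arr = np.asarray(times, dtype=float)
        if times_arr.shape != (len(frames),):
            raise ValueError("times length must match frame count")
        if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames: list[Structure] = list(frames)
        self.times: np.ndarray = times_arr

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    @property
    def topology(self) -> Structure:
        return self.frames[0]

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coords for f in self.frames])

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        """Frames with t_min <= time <= t_max (inclusive analysis window)."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise ValueError(
                f"no frames in window [{t_min}, {t_max}] ns "
                f"(trajectory spans {self.times[0]}-{self.times[-1]} ns)"
            )
        idx = np.nonzero(mask)[0]
        return Trajectory([self.frames[i] for i in idx], self.times[idx])


# ---------------------------------------------------------------------------
# Region maps

RegionRange = tuple[str, int, int]  # (chain, start, end) inclusive

#: Domain and loop boundaries of SHP2 in author numbering of the
#: self-inhibited crystal structure (chain A).
DEFAULT_REGIONS: dict[str, list[RegionRange]] = {
    "N-SH2": [("A", 1, 103)],
    "C-SH2": [("A", 111, 213)],
    "PTP": [("A", 253, 529)],
    "E6": [("A", 215, 252)],
    "DE_loop": [("A", 58, 62)],
    "EF_loop": [("A", 66, 68)],
    "BG_loop": [("A", 89, 92)],
    "loop_34_40": [("A", 34, 40)],
    "linker": [("A", 104, 110)],
}


class RegionMap:
    """Named residue ranges, 1-based inclusive, PDB author numbering."""

    def __init__(self, regions: dict[str, list[RegionRange]] | None = None) -> None:
        self.regions: dict[str, list[RegionRange]] = {}
        for name, ranges in (regions or DEFAULT_REGIONS).items():
            self.regions[name] = []
            for chain, start, end in ranges:
                if start > end:
                    raise ValueError(
                        f"region {name!r}: start {start} > end {end}"
                    )
                self.regions[name].append((chain, int(start), int(end)))

    @classmethod
    def default(cls) -> "RegionMap":
        return cls(DEFAULT_REGIONS)

    @classmethod
    def from_config(cls, text: str) -> "RegionMap":
        """Parse ``name: chain:start-end[,chain:start-end...]`` lines.

        Blank lines and ``#`` comments are ignored. Unknown keys simply
        define new regions; the built-in defaults are not merged in.
        """
        regions: dict[str, list[RegionRange]] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"region config line {lineno}: missing ':'")
            name, _, rest = line.partition(":")
            ranges: list[RegionRange] = []
            for token in rest.split(","):
                token = token.strip()
                try:
                    chain, span = token.split(":")
                    lo, _, hi = span.partition("-")
                    ranges.append((chain.strip(), int(lo), int(hi or lo)))
                except ValueError:
                    raise ValueError(
                        f"region config line {lineno}: bad range {token!r} "
                        "(expected chain:start-end)"
                    ) from None
            regions[name.strip()] = ranges
        return cls(regions)

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def ranges(self, name: str) -> list[RegionRange]:
        try:
            return self.regions[name]
        except KeyError:
            raise SelectionError(f"unknown region {name!r}") from None

    def contains_residue(self, name: str, chain: str, residue_number: int) -> bool:
        return any(
            c == chain and lo <= residue_number <= hi
            for c, lo, hi in self.ranges(name)
        )

    def residues(self, name: str) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for chain, lo, hi in self.ranges(name):
            out.update((chain, r) for r in range(lo, hi + 1))
        return out

    def mask(self, structure: Structure, names: Iterable[str]) -> np.ndarray:
        """Boolean mask over ``structure.atoms`` for the named regions."""
        names = list(names)
        wanted: set[tuple[str, int]] = set()
        for n in names:
            wanted |= self.residues(n)
        return np.array(
            [(a.chain, a.residue_number) in wanted for a in structure.atoms],
            dtype=bool,
        )


def select(
    structure: Structure, region_map: RegionMap, names: str | Iterable[str]
) -> Structure:
    """Atoms whose (chain, residue_number) fall in any named range.

    Original atom order is preserved; an empty result is an error so a
    typo'd chain id cannot silently produce a vacuous analysis.
    """
    if isinstance(names, str):
        names = [names]
    mask = region_map.mask(structure, names)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise SelectionError(
            f"selection {list(names)} matches no atoms in {structure.label!r}"
        )
    return structure.subset(idx.tolist(), label=f"{structure.label}[{','.join(names)}]")


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_record(
    line: str, lineno: int, default_radius: float
) -> tuple[Atom, str, float]:
    """Parse one ATOM/HETATM line -> (atom, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip() or " "
        residue_number = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_str = line[54:60].strip()
        occupancy = float(occ_str) if occ_str else 1.0
        b_str = line[60:66].strip()
        bfactor = float(b_str) if b_str else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from None
    if icode:
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported; "
            "renumber the structure first"
        )
    if not element:
        element = element_from_atom_name(name)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=np.array([x, y, z]),
        vdw_radius=vdw_radius(element, default_radius),
        bfactor=bfactor,
    )
    return atom, altloc, occupancy


def _resolve_altlocs(
    records: list[tuple[Atom, str, float]],
) -> list[Atom]:
    """Keep the highest-occupancy alternate location per atom identity."""
    out: list[Atom] = []
    best: dict[AtomIdentity, tuple[int, float]] = {}  # identity -> (slot, occ)
    for atom, altloc, occ in records:
        key = atom.identity
        if key not in best:
            best[key] = (len(out), occ)
            out.append(atom)
        else:
            slot, kept_occ = best[key]
            if not altloc:
                raise PDBParseError(
                    f"duplicate atom {key} without alternate-location code"
                )
            if occ > kept_occ:
                out[slot] = atom
                best[key] = (slot, occ)
    return out


def read_pdb(
    path: str | Path,
    times: Sequence[float] | None = None,
    default_radius: float = 1.70,
) -> Trajectory:
    """Read a PDB file into a Trajectory, one frame per MODEL.

    A bare coordinate block (no MODEL records) becomes a single frame.
    Alternate locations keep the highest-occupancy conformer; hydrogens
    are retained (they are ignored later by the heavy-atom analyses).
    Frame times default to index x 0.005 ns, the conformer recording
    interval of the analyzed simulations.
    """
    path = Path(path)
    text = path.read_text()
    label = path.stem
    model_records: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                raise PDBParseError(f"line {lineno}: MODEL inside coordinate block")
            in_model = True
            saw_model = True
        elif rec == "ENDMDL":
            if not in_model:
                raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
            model_records.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_record(line, lineno, default_radius))
        elif rec.startswith("END") and not in_model:
            break
    if in_model:
        raise PDBParseError("file ends inside an open MODEL block")
    if current:
        if saw_model:
            raise PDBParseError("coordinate records outside MODEL blocks")
        model_records.append(current)
    if not model_records or not any(model_records):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    frames = [
        Structure(_resolve_altlocs(records), label=f"{label}|{i + 1}")
        for i, records in enumerate(model_records)
    ]
    try:
        return Trajectory(frames, times)
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from None


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: one-letter elements start in column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(trajectory: Trajectory | Structure, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (single frame: bare block).

    Coordinates round-trip through :func:`read_pdb` to 10^-3 A; identity
    fields round-trip exactly.
    """
    if isinstance(trajectory, Structure):
        trajectory = Trajectory([trajectory], times=[0.0])
    lines: list[str] = []
    multi = len(trajectory) > 1
    for i, frame in enumerate(trajectory.frames):
        if multi:
            lines.append(f"MODEL     {i + 1:4d}")
        for atom in frame.atoms:
            if not (-999.999 <= min(atom.position) and max(atom.position) <= 9999.999):
                raise ValueError("coordinate out of fixed-width PDB range")
            name4 = _format_atom_name(atom.name, atom.element)
            lines.append(
                f"ATOM  {atom.serial % 100000:5d} {name4}"
                f" {atom.residue_name:>3s} {atom.chain:1.1s}"
                f"{atom.residue_number:4d}    "
                f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}"
                f"{atom.position[2]:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection predicates

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def backbone_predicate(atom: Atom) -> bool:
    return atom.name in BACKBONE_ATOMS


def ca_predicate(atom: Atom) -> bool:
    return atom.name == "CA"


def heavy_predicate(atom: Atom) -> bool:
    return atom.is_heavy


def predicate_mask(structure: Structure, predicate: Callable[[Atom], bool]) -> np.ndarray:
    return np.array([bool(predicate(a)) for a in structure.atoms], dtype=bool)
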