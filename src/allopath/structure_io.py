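"""Conformational-ensemble and tabular I/O.

The central container is :class:`Ensemble`: an ordered stack of coordinate
frames sharing one atom topology, read from and written to multi-model PDB
files (``MODEL``/``ENDMDL``).  Residues are always addressed by author keys
``(chain_id, residue_number, insertion_code)`` — never by sequential index —
so selections survive renumbering gaps and insertion codes.

Tabular inputs (per-frame MM-PBSA component energies, docking scores with
active/decoy labels, residue selections) are delimited text with required
headers; see :func:`read_energy_table`, :func:`read_score_table` and
:meth:`ResidueSelection.from_tsv`.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Ensemble",
    "ResidueSelection",
    "StructureIOError",
    "TopologyMismatchError",
    "SelectionError",
    "TableSchemaError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_energy_table",
    "read_score_table",
    "select_residues",
    "residue_keys",
]

#: Heavy backbone atom names of standard amino-acid residues.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Required columns of an MM-PBSA component-energy table (kcal/mol).
ENERGY_COLUMNS = ("E_vdw", "E_ele", "E_int", "G_psolv", "G_npsolv")

#: Required columns of a docking-score table.
SCORE_COLUMNS = ("ligand_id", "score", "label")


class StructureIOError(ValueError):
    """Malformed structure file or unparseable record."""


class TopologyMismatchError(StructureIOError):
    """Frames of a multi-model file do not share one atom topology."""


class SelectionError(KeyError):
    """A residue selection entry cannot be resolved against a topology."""


class TableSchemaError(ValueError):
    """A delimited table is missing required columns or malformed."""


@dataclass(frozen=True)
class AtomRecord:
    """Metadata of one atom, shared by every frame of an ensemble."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def identity(self) -> tuple:
        """Key used when comparing topologies across frames."""
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.residue_name, self.atom_name)


@dataclass
class Ensemble:
    """Ordered conformational frames over a shared atom topology.

    Parameters
    ----------
    topology
        One :class:`AtomRecord` per atom, in file/frame order.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    frame_interval
        Optional time between consecutive frames, in ps.
    """

    topology: list[AtomRecord]
    coords: np.ndarray
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"coords has {self.coords.shape[1]} atoms but topology has "
                f"{len(self.topology)}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset_frames(self, indices: Sequence[int]) -> "Ensemble":
        return Ensemble(self.topology, self.coords[np.asarray(indices, int)],
                        self.frame_interval)


@dataclass
class ResidueSelection:
    """A named list of residues, e.g. a binding-pocket lining.

    ``entries`` are ``(chain_id, residue_number, residue_name-or-None)``
    tuples; residue names, when given, are cross-checked at resolution time.
    ``numbering`` optionally maps residue keys to display labels such as
    Ballesteros–Weinstein strings ("5.34"); it never drives selection.
    """

    entries: list[tuple[str, int, str | None]]
    label: str = ""
    numbering: Mapping[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for chain, num, _ in self.entries:
            if (chain, num) in seen:
                raise ValueError(f"duplicate selection entry {chain}/{num}")
            seen.add((chain, num))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "ResidueSelection":
        """Read a ``chain, resnum[, resname]`` TSV (header optional)."""
        entries: list[tuple[str, int, str | None]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if row[0].strip().lower() in ("chain", "chain_id"):
                    continue
                chain = row[0].strip()
                resnum = int(row[1])
                resname = row[2].strip() if len(row) > 2 and row[2].strip() else None
                entries.append((chain, resnum, resname))
        return cls(entries, label=label or str(path))

    @classmethod
    def from_residue_keys(cls, keys: Iterable[tuple[str, int]],
                          label: str = "") -> "ResidueSelection":
        return cls([(c, n, None) for c, n in keys], label=label)


# ---------------------------------------------------------------------------
# PDB reading / writing


def read_multimodel_pdb(path, *, keep_hetero: bool = True,
                        keep_waters: bool = False) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Alternate locations are collapsed to a single conformer per atom by
    keeping the highest occupancy (ties: altloc ``'A'``, then lexicographic).
    Waters (HOH/WAT) are dropped unless ``keep_waters``; other HETATM records
    are kept unless ``keep_hetero`` is false.

    Raises
    ------
    StructureIOError
        On a malformed ATOM/HETATM record (message carries the line number).
    TopologyMismatchError
        If any MODEL's atom set differs from the first MODEL's.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("ensemble", str(path))
    except PDBConstructionException as exc:
        raise StructureIOError(f"malformed PDB record in {path}: {exc}") from exc

    frames: list[list[tuple]] = []   # per model: (identity, record, xyz)
    for model in structure:
        atoms: list[tuple] = []
        for chain in model:
            for residue in chain:
                hetflag, resnum, icode = residue.id
                is_water = hetflag == "W" or residue.resname.strip() in ("HOH", "WAT")
                is_het = hetflag.strip() != ""
                if is_water and not keep_waters:
                    continue
                if is_het and not is_water and not keep_hetero:
                    continue
                for atom in residue:
                    best = atom
                    if atom.is_disordered():
                        best = _pick_altloc(atom)
                    rec = AtomRecord(
                        serial=int(best.serial_number or 0),
                        atom_name=best.get_name(),
                        element=(best.element or "").strip() or _guess_element(best.get_name()),
                        residue_name=residue.resname.strip(),
                        chain_id=chain.id.strip() or " ",
                        residue_number=int(resnum),
                        insertion_code=icode.strip(),
                        occupancy=float(best.get_occupancy() or 1.0),
                        altloc=(best.get_altloc() or "").strip(),
                        hetero=is_het,
                    )
                    atoms.append((rec.identity, rec, np.asarray(best.coord, float)))
        frames.append(atoms)

    if not frames or not frames[0]:
        raise StructureIOError(f"no atoms parsed from {path}")

    ref_ids = [a[0] for a in frames[0]]
    for m, atoms in enumerate(frames[1:], start=2):
        ids = [a[0] for a in atoms]
        if ids != ref_ids:
            offender = _first_difference(ref_ids, ids)
            raise TopologyMismatchError(
                f"MODEL {m} atom set differs from MODEL 1; first mismatch at {offender}")

    topology = [a[1] for a in frames[0]]
    coords = np.stack([np.array([a[2] for a in atoms]) for atoms in frames])
    return Ensemble(topology, coords)


def _pick_altloc(disordered):
    """Highest occupancy wins; ties prefer altloc 'A', then lexicographic."""
    children = sorted(
        disordered.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0),
                       (a.get_altloc() or "") != "A",
                       a.get_altloc() or ""),
    )
    return children[0]


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return name[:2].capitalize()
    return name[:1].upper()


def _first_difference(ref: list, other: list):
    for i, (a, b) in enumerate(zip(ref, other)):
        if a != b:
            return f"atom {i}: {a} vs {b}"
    return f"atom count {len(ref)} vs {len(other)}"


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB (3-decimal Å).

    Raises :class:`StructureIOError` if a residue number exceeds the PDB
    fixed-width field (9999) or a serial exceeds 99999.
    """
    for rec in ensemble.topology:
        if rec.residue_number > 9999 or rec.residue_number < -999:
            raise StructureIOError(
                f"residue number {rec.residue_number} exceeds the PDB format field")
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, rec in enumerate(ensemble.topology):
            x, y, z = ensemble.coords[f, i]
            serial = (i + 1) % 100000
            name = rec.atom_name
            # PDB atom-name alignment: columns 13-16, element right-justified
            if len(name) < 4 and len(rec.element) == 1:
                name = f" {name:<3s}"
            else:
                name = f"{name:<4s}"
            record = "HETATM" if rec.hetero else "ATOM  "
            lines.append(
                f"{record}{serial:5d} {name}{(rec.altloc or ' ')[:1]}"
                f"{rec.residue_name:>3s} {rec.chain_id[:1]}"
                f"{rec.residue_number:4d}{(rec.insertion_code or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{0.0:6.2f}"
                f"          {rec.element:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Tables


def _read_delimited(path) -> pd.DataFrame:
    """Read a TSV/CSV with delimiter auto-detection."""
    with open(path) as fh:
        head = fh.read(4096)
    if not head.strip():
        raise TableSchemaError(f"{path} is empty")
    try:
        dialect = csv.Sniffer().sniff(head.splitlines()[0], delimiters="\t,;")
        sep = dialect.delimiter
    except csv.Error:
        sep = "\t"
    return pd.read_csv(path, sep=sep)


def read_energy_table(path) -> pd.DataFrame:
    """Read per-frame MM-PBSA component energies.

    Required columns: ``E_vdw, E_ele, E_int, G_psolv, G_npsolv`` (kcal/mol).
    Extra columns are preserved (per-residue decomposition, frame index, ...).
    """
    df = _read_delimited(path)
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"energy table {path} missing column(s) {missing}")
    if len(df) == 0:
        raise TableSchemaError(f"energy table {path} has a header but no rows")
    for col in ENERGY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = int((vals.isna()).idxmax())
            raise TableSchemaError(
                f"energy table {path}: non-numeric or missing value in column "
                f"{col!r} at data row {row}")
        df[col] = vals.astype(float)
    return df


def read_score_table(path) -> pd.DataFrame:
    """Read a docking-score table: ``ligand_id, score, label``.

    ``label`` must be ``active`` or ``decoy``; ``score`` is numeric with the
    lower-is-better docking convention left to the consumer.  A table with a
    single label class is accepted here (ROC construction rejects it later).
    """
    df = _read_delimited(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"score table {path} missing column(s) {missing}")
    if len(df) == 0:
        raise TableSchemaError(f"score table {path} has a header but no rows")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(scores.isna().idxmax())
        raise TableSchemaError(f"score table {path}: non-numeric score at data row {row}")
    df["score"] = scores.astype(float)
    df["label"] = df["label"].astype(str).str.strip().str.lower()
    bad_labels = set(df["label"]) - {"active", "decoy"}
    if bad_labels:
        raise TableSchemaError(f"score table {path}: unknown label(s) {sorted(bad_labels)}")
    dupes = df["ligand_id"][df["ligand_id"].duplicated()]
    if len(dupes):
        raise TableSchemaError(
            f"score table {path}: duplicate ligand_id {dupes.iloc[0]!r}")
    return df


# ---------------------------------------------------------------------------
# Residue selection resolution


def residue_keys(topology: Sequence[AtomRecord]) -> list[tuple[str, int, str]]:
    """Ordered unique residue keys ``(chain, resnum, icode)`` of a topology."""
    keys: list[tuple[str, int, str]] = []
    seen = set()
    for rec in topology:
        if rec.residue_key not in seen:
            seen.add(rec.residue_key)
            keys.append(rec.residue_key)
    return keys


_ATOM_CLASSES = ("all", "backbone", "calpha", "sidechain")


def select_residues(topology: Sequence[AtomRecord],
                    selection: ResidueSelection,
                    atoms: str = "all",
                    include_hydrogens: bool = False,
                    ) -> dict[tuple[str, int, str], np.ndarray]:
    """Resolve a residue selection to atom indices, grouped by residue.

    Parameters
    ----------
    atoms
        ``"all"``, ``"backbone"`` (N, CA, C, O), ``"calpha"``, or
        ``"sidechain"`` (everything else, heavy atoms unless
        ``include_hydrogens``).

    Raises
    ------
    SelectionError
        If an entry is absent from the topology or its residue name
        disagrees with the topology's.
    """
    if atoms not in _ATOM_CLASSES:
        raise ValueError(f"atoms must be one of {_ATOM_CLASSES}, got {atoms!r}")

    by_residue: dict[tuple[str, int], list[int]] = {}
    names: dict[tuple[str, int], str] = {}
    full_keys: dict[tuple[str, int], tuple[str, int, str]] = {}
    for i, rec in enumerate(topology):
        short = (rec.chain_id, rec.residue_number)
        by_residue.setdefault(short, []).append(i)
        names.setdefault(short, rec.residue_name)
        full_keys.setdefault(short, rec.residue_key)

    out: dict[tuple[str, int, str], np.ndarray] = {}
    for chain, resnum, resname in selection.entries:
        short = (chain, resnum)
        if short not in by_residue:
            raise SelectionError(
                f"residue {chain}/{resnum} not found in topology "
                f"(selection {selection.label!r})")
        if resname is not None and names[short] != resname:
            raise SelectionError(
                f"residue {chain}/{resnum} is {names[short]}, selection says {resname}")
        idx = []
        for i in by_residue[short]:
            rec = topology[i]
            if not include_hydrogens and rec.element.upper() == "H":
                continue
            if atoms == "backbone" and rec.atom_name not in BACKBONE_ATOMS:
                continue
            if atoms == "calpha" and rec.atom_name != "CA":
                continue
            if atoms == "sidechain" and rec.atom_name in BACKBONE_ATOMS:
                continue
            idx.append(i)
        out[full_keys[short]] = np.asarray(idx, dtype=int)
    return out


def flat_indices(groups: Mapping[tuple, np.ndarray]) -> np.ndarray:
    """Flatten a residue-grouped index mapping into one sorted index array."""
    if not groups:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate([np.asarray(v, int) for v in groups.values()]))
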