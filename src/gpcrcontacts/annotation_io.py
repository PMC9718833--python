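"""Readers/writers and shared naming conventions for the contact pipeline.

Coordinates are Ångström throughout; frame indices are 0-based and frame
windows are half-open ``[start, end)``. A residue is identified by
``(chain, resnum)``; insertion codes are rejected because MD-derived PDB
files do not carry them. Generic residue numbers (GPCRdb ``3x53`` style on
the receptor side, CGN ``G.H5.16`` style on the Gα side) are consumed from
user-provided TSV tables and never computed from structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    FormatError,
    RangeError,
    SelectionError,
    TopologyError,
    ValidationError,
)

#: Atom names treated as backbone; every other atom counts as sidechain.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Gα subfamilies recognised in coupling tables.
SUBFAMILIES = ("Gs", "Gi", "Gq", "G12/13")

#: Coupling datasets and their provenance.
DATASET_IDS = ("AVET", "GTP", "INOUE")

#: Categorical coupling vocabulary.
COUPLING_CATEGORIES = ("primary", "secondary", "none")

GPCR_SIDE = "GPCR"
GPROT_SIDE = "GPROT"


class ResidueKey(NamedTuple):
    chain: str
    resnum: int
    resname: str


@dataclass(frozen=True)
class Atom:
    atom_name: str
    element: str
    residue_key: ResidueKey
    is_sidechain: bool
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValidationError(f"atom {self.atom_name} has empty element")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.atom_name} has non-finite coordinates")


@dataclass
class Topology:
    """Ordered atom list plus named residue selections (e.g. gpcr/galpha)."""

    atoms: list[Atom]
    selections: dict[str, frozenset[ResidueKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for atom in self.atoms:
            key = (atom.residue_key.chain, atom.residue_key.resnum)
            name = atom.residue_key.resname
            if seen.setdefault(key, name) != name:
                raise ValidationError(f"residue {key} has conflicting names")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self, selection: str | None = None) -> list[ResidueKey]:
        keys: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        wanted = self.selections.get(selection) if selection else None
        if selection is not None and wanted is None:
            raise SelectionError(f"unknown selection {selection!r}")
        for atom in self.atoms:
            rk = atom.residue_key
            if rk in seen:
                continue
            if wanted is not None and rk not in wanted:
                continue
            seen.add(rk)
            keys.append(rk)
        return keys

    def atom_indices(self, selection: str) -> list[int]:
        wanted = self.selections.get(selection)
        if wanted is None:
            raise SelectionError(f"unknown selection {selection!r}")
        return [i for i, a in enumerate(self.atoms) if a.residue_key in wanted]

    def check_disjoint(self, sel_a: str = "gpcr", sel_b: str = "galpha") -> None:
        a = self.selections.get(sel_a)
        b = self.selections.get(sel_b)
        if not a or not b:
            raise SelectionError(f"selections {sel_a!r}/{sel_b!r} missing or empty")
        if a & b:
            raise SelectionError("analysis selections overlap")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[np.ndarray]  # each (n_atoms, 3) float64, Å
    frame_ids: list[int]
    system_id: str = "system"

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for f in self.frames:
            if f.shape != (n, 3):
                raise TopologyError(
                    f"frame has {f.shape[0]} coordinates for {n} topology atoms"
                )
        if list(self.frame_ids) != sorted(set(self.frame_ids)):
            raise ValidationError("frame_ids must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class MapEntry:
    generic: str
    sse: str
    side: str


@dataclass
class NumberingMap:
    """Residue → (generic number, SSE, side) lookup for one system."""

    entries: dict[tuple[str, int], MapEntry]

    def __post_init__(self) -> None:
        for side in (GPCR_SIDE, GPROT_SIDE):
            generics = [e.generic for e in self.entries.values() if e.side == side]
            if len(generics) != len(set(generics)):
                raise ValidationError(f"duplicate generic numbers on side {side}")
        for e in self.entries.values():
            if not e.generic:
                raise ValidationError("empty generic number in map")
            if e.side not in (GPCR_SIDE, GPROT_SIDE):
                raise ValidationError(f"unknown side {e.side!r}")

    def get(self, chain: str, resnum: int) -> MapEntry | None:
        return self.entries.get((chain, resnum))

    def sse_of_generic(self, generic: str, side: str) -> str | None:
        for e in self.entries.values():
            if e.side == side and e.generic == generic:
                return e.sse
        return None

    def generics(self, side: str) -> set[str]:
        return {e.generic for e in self.entries.values() if e.side == side}


@dataclass
class CouplingRecord:
    receptor: str
    subfamily: str
    category: str | None = None
    emax: float | None = None


@dataclass
class CouplingTable:
    dataset_id: str
    records: list[CouplingRecord]

    def __post_init__(self) -> None:
        if self.dataset_id not in DATASET_IDS:
            raise ValidationError(f"unknown dataset id {self.dataset_id!r}")
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            if r.subfamily not in SUBFAMILIES:
                raise ValidationError(f"unknown subfamily {r.subfamily!r}")
            if (r.receptor, r.subfamily) in seen:
                raise ValidationError(
                    f"duplicate coupling value for {(r.receptor, r.subfamily)}"
                )
            seen.add((r.receptor, r.subfamily))
            if r.emax is not None and not np.isfinite(r.emax):
                raise ValidationError("non-finite Emax")


# ---------------------------------------------------------------------------
# PDB topology / trajectory reading (Biopython; XTC/DCD through MDAnalysis)
# ---------------------------------------------------------------------------

def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip()
    if not elem:
        # fall back on the leading letter of the atom name
        name = bio_atom.get_name().lstrip("0123456789")
        elem = name[:1]
    return elem.upper()


def read_topology(
    path: str | Path,
    gpcr_chain: str | None = None,
    galpha_chain: str | None = None,
) -> Topology:
    """Parse a PDB file into a :class:`Topology`.

    ``gpcr_chain``/``galpha_chain`` configure the two analysis selections by
    chain identifier; both must be present and non-empty when given.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("topology", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"no models in PDB file {path}")
    model = models[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag.strip():
                continue  # waters/ligands are outside the analysis selections
            if icode.strip():
                raise FormatError(
                    f"insertion code {icode!r} at {chain.id}{resnum} unsupported"
                )
            rk = ResidueKey(chain.id, int(resnum), res.get_resname())
            for bio_atom in res:
                name = bio_atom.get_name()
                atoms.append(
                    Atom(
                        atom_name=name,
                        element=_element_of(bio_atom),
                        residue_key=rk,
                        is_sidechain=name not in BACKBONE_ATOM_NAMES,
                        coords=tuple(float(x) for x in bio_atom.coord),
                    )
                )
    if not atoms:
        raise FormatError(f"no protein atoms found in {path}")

    selections: dict[str, frozenset[ResidueKey]] = {}
    for sel_name, chain_id in (("gpcr", gpcr_chain), ("galpha", galpha_chain)):
        if chain_id is None:
            continue
        keys = frozenset(
            a.residue_key for a in atoms if a.residue_key.chain == chain_id
        )
        if not keys:
            raise SelectionError(f"chain {chain_id!r} for {sel_name!r} is empty")
        selections[sel_name] = keys
    topo = Topology(atoms=atoms, selections=selections)
    if "gpcr" in selections and "galpha" in selections:
        topo.check_disjoint()
    return topo


def _pdb_model_coords(path: Path, topology: Topology) -> list[np.ndarray]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frames", str(path))
    frames = []
    for model in structure:
        coords = []
        for chain in model:
            for res in chain:
                if res.id[0].strip():
                    continue
                for bio_atom in res:
                    coords.append(bio_atom.coord)
        arr = np.asarray(coords, dtype=float)
        if arr.shape[0] != topology.n_atoms:
            raise TopologyError(
                f"{path} frame has {arr.shape[0]} atoms, topology has "
                f"{topology.n_atoms}"
            )
        frames.append(arr)
    return frames


def _mda_coords(path: Path, topology_path: str | Path, topology: Topology) -> list[np.ndarray]:
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path), str(path))
    if len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"{path} has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
        )
    return [u.atoms.positions.astype(float).copy() for _ in u.trajectory]


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: Topology,
    frame_range: tuple[int, int] | None = None,
    system_id: str = "system",
    topology_path: str | Path | None = None,
) -> Trajectory:
    """Read one or more trajectory files into a concatenated ensemble.

    The half-open ``frame_range`` window is applied to each replicate file
    before concatenation (replicate order, then frame order), mirroring the
    practice of pooling the terminal window of every replicate into one
    ensemble. Multi-model PDB is always supported; XTC/DCD files additionally
    require ``topology_path`` and go through MDAnalysis.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if frame_range is not None:
        start, end = frame_range
        if end <= start:
            raise RangeError(f"empty frame window [{start}, {end})")

    all_frames: list[np.ndarray] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in {".xtc", ".dcd"}:
            if topology_path is None:
                raise FormatError(f"{p.suffix} trajectories need topology_path")
            frames = _mda_coords(p, topology_path, topology)
        else:
            frames = _pdb_model_coords(p, topology)
        if frame_range is not None:
            frames = frames[frame_range[0] : frame_range[1]]
        all_frames.extend(frames)
    if not all_frames:
        raise RangeError("frame window selected no frames")
    return Trajectory(
        topology=topology,
        frames=all_frames,
        frame_ids=list(range(len(all_frames))),
        system_id=system_id,
    )


# ---------------------------------------------------------------------------
# Tabular readers/writers
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["chain", "resnum", "generic", "sse", "side"]


def read_numbering_map(path: str | Path) -> NumberingMap:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "generic": str, "sse": str, "side": str})
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"numbering map missing columns {missing}")
    entries: dict[tuple[str, int], MapEntry] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chain), int(row.resnum))
        if key in entries:
            raise ValidationError(f"duplicate residue {key} in numbering map")
        entries[key] = MapEntry(generic=str(row.generic), sse=str(row.sse), side=str(row.side))
    return NumberingMap(entries=entries)


def write_numbering_map(nmap: NumberingMap, path: str | Path) -> None:
    rows = [
        {"chain": c, "resnum": r, "generic": e.generic, "sse": e.sse, "side": e.side}
        for (c, r), e in nmap.entries.items()
    ]
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_coupling_table(path: str | Path, dataset_id: str) -> CouplingTable:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("receptor", "subfamily", "value"):
        if col not in df.columns:
            raise ValidationError(f"coupling table missing column {col!r}")
    records: list[CouplingRecord] = []
    for row in df.itertuples(index=False):
        value = row.value
        rec = CouplingRecord(receptor=str(row.receptor), subfamily=str(row.subfamily))
        if isinstance(value, str) and not _is_number(value):
            cat = value.strip().lower()
            if cat in ("no coupling", "non-coupler", "nc"):
                cat = "none"
            if cat not in COUPLING_CATEGORIES:
                raise ValidationError(f"unknown coupling category {value!r}")
            rec.category = cat
        else:
            rec.emax = float(value)
        records.append(rec)
    return CouplingTable(dataset_id=dataset_id, records=records)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_coupling_table(table: CouplingTable, path: str | Path) -> None:
    rows = [
        {
            "receptor": r.receptor,
            "subfamily": r.subfamily,
            "value": r.emax if r.emax is not None else r.category,
        }
        for r in table.records
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# -- timeline, fingerprint, frequency, label tables --------------------------

TIMELINE_COLUMNS = ["frame_id", "gpcr_generic", "gprot_generic", "contact_type"]


def write_timeline_tsv(timeline, path: str | Path) -> None:
    """Write a contact timeline as TSV (frame_id, generics, contact type)."""
    rows = [
        {
            "frame_id": e.frame_id,
            "gpcr_generic": e.gpcr_generic,
            "gprot_generic": e.gprot_generic,
            "contact_type": e.contact_type,
        }
        for e in timeline.events
    ]
    df = pd.DataFrame(rows, columns=TIMELINE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# system_id={timeline.system_id}\tn_frames={timeline.n_frames}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_timeline_tsv(path: str | Path):
    from .contact_detection import ContactEvent, ContactTimeline

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("timeline TSV missing metadata header line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", dtype={"gpcr_generic": str, "gprot_generic": str})
    events = [
        ContactEvent(
            frame_id=int(r.frame_id),
            gpcr_generic=str(r.gpcr_generic),
            gprot_generic=str(r.gprot_generic),
            contact_type=str(r.contact_type),
        )
        for r in df.itertuples(index=False)
    ]
    return ContactTimeline(
        system_id=meta["system_id"], events=events, n_frames=int(meta["n_frames"])
    )


def write_fingerprint_tsv(matrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_fingerprint_tsv(path: str | Path):
    from .fingerprints import FingerprintMatrix

    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in ("system_id", "class_label", "frame_id") if c in df.columns]
    pair_cols = [c for c in df.columns if c not in meta_cols]
    data = df[pair_cols].to_numpy(dtype=np.uint8)
    n = len(df)
    return FingerprintMatrix(
        pairs=list(pair_cols),
        data=data,
        system_ids=np.asarray(df["system_id"] if "system_id" in df else ["system"] * n, dtype=object),
        class_labels=np.asarray(df["class_label"] if "class_label" in df else ["other"] * n, dtype=object),
        frame_ids=np.asarray(df["frame_id"] if "frame_id" in df else np.arange(n), dtype=int),
    )


def write_frequency_tsv(freq: pd.DataFrame, path: str | Path) -> None:
    """Frequency table TSV with columns pair_key, system_id, frequency."""
    long = (
        freq.stack()
        .rename("frequency")
        .reset_index()
        .rename(columns={"level_0": "system_id", "level_1": "pair_key"})
    )
    long.columns = ["system_id", "pair_key", "frequency"]
    long = long[["pair_key", "system_id", "frequency"]]
    long.to_csv(path, sep="\t", index=False)


def read_frequency_tsv(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", dtype={"pair_key": str, "system_id": str})
    wide = long.pivot(index="system_id", columns="pair_key", values="frequency")
    wide.index.name = None
    wide.columns.name = None
    return wide.sort_index(axis=1)
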