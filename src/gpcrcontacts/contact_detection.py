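"""Per-frame sidechain–sidechain intermolecular contact detection.

Five geometric criteria, evaluated over inter-selection sidechain atom
pairs, define a contact between a receptor residue and a Gα residue:

* ``SB``  salt bridge — anion/cation atom distance < 4.0 Å
* ``HB``  hydrogen bond — donor/acceptor heavy-atom distance < 3.5 Å and,
  when hydrogens are present, the D→H vs D→A angle < 70°
* ``VDW`` van der Waals — heavy-atom distance < r_i + r_j + 0.5 Å
* ``PS``  π-stack — aromatic ring centroid distance < 7.0 Å and ring-normal
  angle < 30° (normals are unsigned axes, folded into [0°, 90°])
* ``PC``  cation–π — cation to ring-centroid distance < 6.0 Å and
  normal-to-cation angle < 60° (folded)

All inequalities are strict. The van-der-Waals form follows the widely used
getcontacts convention (sum of radii plus a slack, 0.5 Å by default); the
slack is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotation_io import Atom, NumberingMap, ResidueKey, Trajectory
from .errors import ConfigurationError, SelectionError, ValidationError

log = logging.getLogger(__name__)

CONTACT_TYPES = ("SB", "HB", "VDW", "PS", "PC")

#: Bondi-style van der Waals radii by element symbol, Å.
DEFAULT_VDW_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# Sidechain chemistry tables (atom-name level). The getcontacts tool does
# not document a canonical set, so these explicit tables define ours.
ANION_ATOMS: Mapping[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}
CATION_ATOMS: Mapping[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NH1", "NH2", "NE"}),
}
#: Histidine imidazole nitrogens, treated as cations only when enabled.
HIS_CATION_ATOMS: Mapping[str, frozenset[str]] = {
    "HIS": frozenset({"ND1", "NE2"}),
}
DONOR_ATOMS: Mapping[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}),
}
ACCEPTOR_ATOMS: Mapping[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
}
#: Aromatic ring definitions; TRP contributes both its 5- and 6-membered ring.
RING_ATOMS: Mapping[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}

#: Covalent D–H bond length upper bound used to pair hydrogens to donors, Å.
_DH_BOND_MAX = 1.25


@dataclass(frozen=True)
class ContactCriteria:
    salt_bridge_cutoff: float = 4.0
    hbond_da_cutoff: float = 3.5
    hbond_angle_max: float = 70.0
    vdw_slack: float = 0.5
    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    pistack_centroid_cutoff: float = 7.0
    pistack_angle_max: float = 30.0
    catpi_cutoff: float = 6.0
    catpi_angle_max: float = 60.0
    his_cation: bool = False
    prefilter_cutoff: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "salt_bridge_cutoff",
            "hbond_da_cutoff",
            "pistack_centroid_cutoff",
            "catpi_cutoff",
            "prefilter_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("hbond_angle_max", "pistack_angle_max", "catpi_angle_max"):
            v = getattr(self, name)
            if not 0 < v <= 90:
                raise ConfigurationError(f"{name} must lie in (0, 90]")

    def cation_table(self) -> dict[str, frozenset[str]]:
        table = dict(CATION_ATOMS)
        if self.his_cation:
            table.update(HIS_CATION_ATOMS)
        return table


@dataclass(frozen=True)
class ContactEvent:
    frame_id: int
    gpcr_generic: str
    gprot_generic: str
    contact_type: str
    gpcr_residue: ResidueKey | None = None
    gprot_residue: ResidueKey | None = None

    def __post_init__(self) -> None:
        if self.contact_type not in CONTACT_TYPES:
            raise ValidationError(f"unknown contact type {self.contact_type!r}")

    @property
    def pair_key(self) -> str:
        return f"{self.gpcr_generic}:{self.gprot_generic}"


@dataclass
class ContactTimeline:
    system_id: str
    events: list[ContactEvent]
    n_frames: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.events:
            if not 0 <= e.frame_id < self.n_frames:
                raise ValidationError(
                    f"event frame {e.frame_id} outside [0, {self.n_frames})"
                )
        keys = [(e.frame_id, e.gpcr_generic, e.gprot_generic, e.contact_type) for e in self.events]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate contact events in timeline")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions treated as unsigned axes, in [0°, 90°]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(min(1.0, c)))


def vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def ring_centroid_normal(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit plane centroid and unit normal of a ring (SVD of centered coords)."""
    coords = np.asarray(ring_coords, float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


# ---------------------------------------------------------------------------
# The five criteria
# ---------------------------------------------------------------------------

def _coords(atom_or_array) -> np.ndarray:
    if isinstance(atom_or_array, Atom):
        return np.asarray(atom_or_array.coords, float)
    return np.asarray(atom_or_array, float)


def _ion_applicable(atom: Atom, table: Mapping[str, frozenset[str]]) -> bool:
    names = table.get(atom.residue_key.resname)
    return names is not None and atom.atom_name in names


def is_salt_bridge(anion_atom: Atom, cation_atom: Atom, criteria: ContactCriteria) -> bool:
    # symmetric in argument order: accept (anion, cation) either way round
    cations = criteria.cation_table()
    pair_ok = (
        _ion_applicable(anion_atom, ANION_ATOMS) and _ion_applicable(cation_atom, cations)
    ) or (
        _ion_applicable(cation_atom, ANION_ATOMS) and _ion_applicable(anion_atom, cations)
    )
    if not pair_ok:
        log.debug("salt bridge not applicable: %s/%s", anion_atom.atom_name, cation_atom.atom_name)
        return False
    return _dist(_coords(anion_atom), _coords(cation_atom)) < criteria.salt_bridge_cutoff


def is_hbond(
    donor_heavy: Atom,
    donor_hydrogen: Atom | None,
    acceptor_heavy: Atom,
    criteria: ContactCriteria,
) -> bool:
    if not (
        _ion_applicable(donor_heavy, DONOR_ATOMS)
        and _ion_applicable(acceptor_heavy, ACCEPTOR_ATOMS)
    ):
        return False
    d = _coords(donor_heavy)
    a = _coords(acceptor_heavy)
    if _dist(d, a) >= criteria.hbond_da_cutoff:
        return False
    if donor_hydrogen is None:
        return True  # heavy-atom mode: distance criterion alone
    h = _coords(donor_hydrogen)
    return vector_angle_deg(h - d, a - d) < criteria.hbond_angle_max


def is_vdw(atom_i: Atom, atom_j: Atom, criteria: ContactCriteria) -> bool:
    radii = criteria.vdw_radii
    try:
        ri = radii[atom_i.element.upper()]
        rj = radii[atom_j.element.upper()]
    except KeyError as exc:
        raise ConfigurationError(f"no van der Waals radius for element {exc}") from exc
    return _dist(_coords(atom_i), _coords(atom_j)) < ri + rj + criteria.vdw_slack


def is_pistack(ring_i_atoms, ring_j_atoms, criteria: ContactCriteria) -> bool:
    ri = np.asarray([_coords(a) for a in ring_i_atoms], float)
    rj = np.asarray([_coords(a) for a in ring_j_atoms], float)
    if len(ri) < 5 or len(rj) < 5:
        return False  # incompletely resolved ring: not applicable
    ci, ni = ring_centroid_normal(ri)
    cj, nj = ring_centroid_normal(rj)
    if _dist(ci, cj) >= criteria.pistack_centroid_cutoff:
        return False
    return folded_angle_deg(ni, nj) < criteria.pistack_angle_max


def is_cationpi(cation_atom: Atom, ring_atoms, criteria: ContactCriteria) -> bool:
    if isinstance(cation_atom, Atom) and not _ion_applicable(cation_atom, criteria.cation_table()):
        return False
    ring = np.asarray([_coords(a) for a in ring_atoms], float)
    if len(ring) < 5:
        return False
    centroid, normal = ring_centroid_normal(ring)
    cat = _coords(cation_atom)
    if _dist(cat, centroid) >= criteria.catpi_cutoff:
        return False
    return folded_angle_deg(normal, cat - centroid) < criteria.catpi_angle_max


# ---------------------------------------------------------------------------
# Residue-level bookkeeping for trajectory scanning
# ---------------------------------------------------------------------------

@dataclass
class _ResidueView:
    key: ResidueKey
    generic: str
    sidechain_heavy: list[int]  # atom indices into the topology
    anions: list[int]
    cations: list[int]
    donors: list[tuple[int, list[int]]]  # (donor heavy, its hydrogens)
    acceptors: list[int]
    rings: list[list[int]]


def _build_views(
    trajectory: Trajectory,
    numbering_map: NumberingMap,
    selection: str,
    criteria: ContactCriteria,
) -> tuple[list[_ResidueView], int]:
    topo = trajectory.topology
    cations = criteria.cation_table()
    by_res: dict[ResidueKey, list[int]] = {}
    for idx in topo.atom_indices(selection):
        by_res.setdefault(topo.atoms[idx].residue_key, []).append(idx)

    views: list[_ResidueView] = []
    n_unmapped = 0
    base = np.asarray(trajectory.frames[0], float)
    for rk, indices in sorted(by_res.items()):
        entry = numbering_map.get(rk.chain, rk.resnum)
        if entry is None:
            n_unmapped += 1
            continue
        resname = rk.resname
        sidechain = [i for i in indices if topo.atoms[i].is_sidechain]
        heavy = [i for i in sidechain if topo.atoms[i].element.upper() != "H"]
        hydrogens = [i for i in sidechain if topo.atoms[i].element.upper() == "H"]
        donors: list[tuple[int, list[int]]] = []
        for i in heavy:
            if topo.atoms[i].atom_name in DONOR_ATOMS.get(resname, frozenset()):
                hs = [
                    j
                    for j in hydrogens
                    if np.linalg.norm(base[j] - base[i]) < _DH_BOND_MAX
                ]
                donors.append((i, hs))
        rings = []
        for ring_names in RING_ATOMS.get(resname, ()):
            ring_idx = [i for i in heavy if topo.atoms[i].atom_name in ring_names]
            if len(ring_idx) >= 5:
                rings.append(ring_idx)
        views.append(
            _ResidueView(
                key=rk,
                generic=entry.generic,
                sidechain_heavy=heavy,
                anions=[i for i in heavy if topo.atoms[i].atom_name in ANION_ATOMS.get(resname, frozenset())],
                cations=[i for i in heavy if topo.atoms[i].atom_name in cations.get(resname, frozenset())],
                donors=donors,
                acceptors=[i for i in heavy if topo.atoms[i].atom_name in ACCEPTOR_ATOMS.get(resname, frozenset())],
                rings=rings,
            )
        )
    return views, n_unmapped


def _pair_contact_types(
    coords: np.ndarray,
    res_g: _ResidueView,
    res_p: _ResidueView,
    topo_atoms: Sequence[Atom],
    criteria: ContactCriteria,
    hydrogen_mode: bool,
) -> set[str]:
    """Evaluate all five criteria for one residue pair in one frame."""

    def atom_at(i: int) -> Atom:
        return replace(topo_atoms[i], coords=tuple(coords[i]))

    found: set[str] = set()
    # salt bridge, both polarities
    for a, c in ((res_g.anions, res_p.cations), (res_p.anions, res_g.cations)):
        if found.intersection({"SB"}):
            break
        for i in a:
            if any(
                is_salt_bridge(atom_at(i), atom_at(j), criteria) for j in c
            ):
                found.add("SB")
                break
    # hydrogen bond, both directions
    for donors, acceptors in ((res_g.donors, res_p.acceptors), (res_p.donors, res_g.acceptors)):
        if "HB" in found:
            break
        for d_idx, h_idx in donors:
            hs: list[Atom | None] = [atom_at(h) for h in h_idx] if (hydrogen_mode and h_idx) else [None]
            if any(
                is_hbond(atom_at(d_idx), h, atom_at(a_idx), criteria)
                for a_idx in acceptors
                for h in hs
            ):
                found.add("HB")
                break
    # van der Waals over heavy sidechain atoms
    for i in res_g.sidechain_heavy:
        if any(is_vdw(atom_at(i), atom_at(j), criteria) for j in res_p.sidechain_heavy):
            found.add("VDW")
            break
    # pi-stacking
    for ring_i in res_g.rings:
        if "PS" in found:
            break
        for ring_j in res_p.rings:
            if is_pistack(coords[ring_i], coords[ring_j], criteria):
                found.add("PS")
                break
    # cation-pi, both directions
    for cats, rings in ((res_g.cations, res_p.rings), (res_p.cations, res_g.rings)):
        if "PC" in found:
            break
        for c in cats:
            if any(is_cationpi(atom_at(c), coords[ring], criteria) for ring in rings):
                found.add("PC")
                break
    return found


def detect_contacts(
    trajectory: Trajectory,
    numbering_map: NumberingMap,
    criteria: ContactCriteria | None = None,
    sel_gpcr: str = "gpcr",
    sel_gprot: str = "galpha",
    prefilter: bool = True,
) -> ContactTimeline:
    """Scan every frame for inter-selection sidechain contacts.

    A 12 Å sidechain-centroid prefilter (lossless for the default cutoffs)
    limits criterion evaluation to nearby residue pairs; ``prefilter=False``
    forces the O(n²) all-pairs path, which must give identical results.
    Residues without a generic-number entry are excluded and tallied in the
    timeline metadata.
    """
    criteria = criteria or ContactCriteria()
    topo = trajectory.topology
    topo.check_disjoint(sel_gpcr, sel_gprot)

    views_g, unmapped_g = _build_views(trajectory, numbering_map, sel_gpcr, criteria)
    views_p, unmapped_p = _build_views(trajectory, numbering_map, sel_gprot, criteria)
    if not any(v.sidechain_heavy for v in views_g) or not any(v.sidechain_heavy for v in views_p):
        raise SelectionError("a selection has no mapped sidechain heavy atoms")

    hydrogen_mode = any(
        a.element.upper() == "H" and a.is_sidechain for a in topo.atoms
    )

    events: list[ContactEvent] = []
    for frame_pos, coords in enumerate(trajectory.frames):
        coords = np.asarray(coords, float)
        frame_id = trajectory.frame_ids[frame_pos]
        if prefilter:
            cg = np.asarray([coords[v.sidechain_heavy].mean(axis=0) for v in views_g])
            cp = np.asarray([coords[v.sidechain_heavy].mean(axis=0) for v in views_p])
            tree_g, tree_p = cKDTree(cg), cKDTree(cp)
            candidate_pairs = [
                (ig, ip)
                for ig, near in enumerate(
                    tree_g.query_ball_tree(tree_p, criteria.prefilter_cutoff)
                )
                for ip in near
            ]
        else:
            candidate_pairs = [
                (ig, ip) for ig in range(len(views_g)) for ip in range(len(views_p))
            ]
        for ig, ip in candidate_pairs:
            vg, vp = views_g[ig], views_p[ip]
            for ctype in sorted(
                _pair_contact_types(coords, vg, vp, topo.atoms, criteria, hydrogen_mode)
            ):
                events.append(
                    ContactEvent(
                        frame_id=frame_id,
                        gpcr_generic=vg.generic,
                        gprot_generic=vp.generic,
                        contact_type=ctype,
                        gpcr_residue=vg.key,
                        gprot_residue=vp.key,
                    )
                )
    events.sort(key=lambda e: (e.frame_id, e.gpcr_generic, e.gprot_generic, e.contact_type))
    return ContactTimeline(
        system_id=trajectory.system_id,
        events=events,
        n_frames=trajectory.n_frames,
        metadata={
            "hbond_mode": "hydrogen" if hydrogen_mode else "heavy_atom",
            "unmapped_gpcr_residues": unmapped_g,
            "unmapped_gprot_residues": unmapped_p,
        },
    )
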