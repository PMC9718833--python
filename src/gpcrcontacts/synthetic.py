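"""Synthetic test-bed data: planted class-structured fingerprints and toy
3-D receptor:Gα complexes.

The fingerprint generator draws every matrix entry as an independent
Bernoulli variable whose occupancy depends on the pair's planted role —
common contacts persist in every class, subfamily-specific contacts in
exactly one, background pairs are rare everywhere. Frames are temporally
i.i.d. (no autocorrelation), a deliberate simplification of MD frames:
the persistence and discriminant statistics downstream depend only on the
marginal occupancies.

Toy complexes place idealized residues (literature-scale bond lengths, no
rotamer sampling) on two chains at prescribed distances/orientations so
that each geometric contact criterion can be triggered on purpose, then
jitter the coordinates per frame with seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    BACKBONE_ATOM_NAMES,
    Atom,
    ResidueKey,
    Topology,
    Trajectory,
)
from .errors import GenerationError, ParameterError
from .fingerprints import CLASSES, FingerprintMatrix

ROLE_COMMON = "common"
ROLE_BACKGROUND = "background"


def role_specific(cls: str) -> str:
    return f"specific-{cls}"


# ---------------------------------------------------------------------------
# Planted fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpec:
    systems_per_class: int = 2
    n_frames: int = 500
    n_background_pairs: int = 20
    n_common_pairs: int = 5
    n_specific_pairs: int = 3  # per class
    p_common: float = 0.6
    p_specific_own: float = 0.6
    p_specific_other: float = 0.02
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.systems_per_class < 1:
            raise ParameterError("systems_per_class must be >= 1")
        for name in ("n_background_pairs", "n_common_pairs", "n_specific_pairs"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.total_pairs < 1:
            raise ParameterError("at least one contact pair is required")
        for name in ("p_common", "p_specific_own", "p_specific_other", "p_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @property
    def total_pairs(self) -> int:
        return (
            self.n_common_pairs
            + 3 * self.n_specific_pairs
            + self.n_background_pairs
        )


@dataclass
class PlantedFingerprints:
    matrix: FingerprintMatrix
    system_to_class: dict[str, str]
    pair_roles: dict[str, str]  # pair key -> common / specific-X / background
    expected_labels: dict[str, str]  # pair key -> persistence label

    def pairs_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.pair_roles.items() if r == role]


def _planted_pair_keys(spec: PlantedSpec) -> list[tuple[str, str]]:
    """(pair key, role) in generation order; keys mimic real generic numbers."""
    keys: list[tuple[str, str]] = []
    idx = 0

    def next_key() -> str:
        nonlocal idx
        helix = 1 + idx // 9
        pos = 40 + idx % 9
        key = f"{helix}x{pos}:G.H5.{idx + 1}"
        idx += 1
        return key

    for _ in range(spec.n_common_pairs):
        keys.append((next_key(), ROLE_COMMON))
    for cls in CLASSES:
        for _ in range(spec.n_specific_pairs):
            keys.append((next_key(), role_specific(cls)))
    for _ in range(spec.n_background_pairs):
        keys.append((next_key(), ROLE_BACKGROUND))
    return keys


def _occupancy(role: str, cls: str, spec: PlantedSpec) -> float:
    if role == ROLE_COMMON:
        return spec.p_common
    if role == ROLE_BACKGROUND:
        return spec.p_background
    own = role == role_specific(cls)
    return spec.p_specific_own if own else spec.p_specific_other


def generate_fingerprints(spec: PlantedSpec) -> PlantedFingerprints:
    """Draw a class-structured binary fingerprint dataset.

    Reproducible for a given spec+seed; ground-truth pair roles and the
    persistence labels they imply are returned alongside the matrix.
    """
    rng = np.random.default_rng(spec.seed)
    keyed = _planted_pair_keys(spec)
    universe = sorted(k for k, _ in keyed)
    roles = dict(keyed)

    blocks, sys_ids, cls_labels, frame_ids = [], [], [], []
    system_to_class: dict[str, str] = {}
    for cls in CLASSES:
        probs = np.asarray([_occupancy(roles[p], cls, spec) for p in universe])
        for i in range(spec.systems_per_class):
            system = f"{cls}_{i + 1}"
            system_to_class[system] = cls
            blocks.append(
                (rng.random((spec.n_frames, len(universe))) < probs).astype(np.uint8)
            )
            sys_ids.extend([system] * spec.n_frames)
            cls_labels.extend([cls] * spec.n_frames)
            frame_ids.extend(range(spec.n_frames))

    matrix = FingerprintMatrix(
        pairs=universe,
        data=np.vstack(blocks),
        system_ids=np.asarray(sys_ids, dtype=object),
        class_labels=np.asarray(cls_labels, dtype=object),
        frame_ids=np.asarray(frame_ids, dtype=int),
    )
    expected = {
        p: (r if r != ROLE_BACKGROUND else "other") for p, r in roles.items()
    }
    return PlantedFingerprints(
        matrix=matrix,
        system_to_class=system_to_class,
        pair_roles=roles,
        expected_labels=expected,
    )


# ---------------------------------------------------------------------------
# Toy 3-D complexes
# ---------------------------------------------------------------------------

# Residue templates in local coordinates (Å). The functional "anchor" site
# sits at the origin: the charged/polar tip atom for chain-like sidechains,
# the aromatic ring centroid (ring in the xy-plane, normal +z) for ring
# residues. The rest of the residue extends into -x (or -y for rings).

def _chain_template(sidechain: list[tuple[str, tuple[float, float, float]]]):
    """Sidechain atoms (anchor first) plus a backbone trailing in -x."""
    tail_x = min(x for _, (x, _, _) in sidechain) if sidechain else 0.0
    backbone = [
        ("CA", (tail_x - 1.5, 0.4, 0.0)),
        ("N", (tail_x - 2.2, 1.6, 0.3)),
        ("C", (tail_x - 2.6, -0.8, 0.0)),
        ("O", (tail_x - 3.7, -0.6, 0.5)),
    ]
    return sidechain + backbone


def _ring_template(ring_names: Sequence[str], radius: float = 1.39, extra=()):
    """Planar ring centered at the origin in the xy-plane plus backbone."""
    n = len(ring_names)
    atoms = []
    for i, name in enumerate(ring_names):
        ang = 2 * np.pi * i / n - np.pi / 2  # first ring atom (CG) toward -y
        atoms.append((name, (radius * np.cos(ang), radius * np.sin(ang), 0.0)))
    atoms += list(extra)
    atoms += [
        ("CB", (0.0, -2.9, 0.0)),
        ("CA", (0.0, -4.2, 0.6)),
        ("N", (0.9, -5.0, 1.3)),
        ("C", (-1.2, -5.0, 0.4)),
        ("O", (-1.4, -6.2, 0.6)),
    ]
    return atoms


RESIDUE_TEMPLATES: Mapping[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [
        ("CA", (0.0, 0.0, 0.0)),
        ("N", (-0.8, 1.2, 0.0)),
        ("C", (-1.1, -1.0, 0.0)),
        ("O", (-2.3, -1.1, 0.3)),
    ],
    "ALA": _chain_template([("CB", (0.0, 0.0, 0.0))]),
    "SER": _chain_template([("OG", (0.0, 0.0, 0.0)), ("HG", (0.3, 0.0, 1.0)), ("CB", (-1.4, 0.3, 0.0))]),
    "ASP": _chain_template(
        [
            ("OD1", (0.0, 0.0, 0.0)),
            ("CG", (-0.8, 1.0, 0.0)),
            ("OD2", (-0.4, 2.2, 0.2)),
            ("CB", (-2.3, 0.9, 0.0)),
        ]
    ),
    "GLU": _chain_template(
        [
            ("OE1", (0.0, 0.0, 0.0)),
            ("CD", (-0.8, 1.0, 0.0)),
            ("OE2", (-0.4, 2.2, 0.2)),
            ("CG", (-2.3, 0.9, 0.0)),
            ("CB", (-3.1, 2.1, 0.2)),
        ]
    ),
    "LYS": _chain_template(
        [
            ("NZ", (0.0, 0.0, 0.0)),
            ("CE", (-1.4, 0.4, 0.0)),
            ("CD", (-2.4, -0.7, 0.0)),
            ("CG", (-3.8, -0.3, 0.2)),
            ("CB", (-4.8, -1.4, 0.2)),
        ]
    ),
    "ARG": _chain_template(
        [
            ("NH1", (0.0, 0.0, 0.0)),
            ("CZ", (-0.8, 1.1, 0.0)),
            ("NH2", (-0.3, 2.3, 0.2)),
            ("NE", (-2.1, 1.0, 0.0)),
            ("CD", (-3.0, 2.1, 0.2)),
            ("CG", (-4.4, 1.7, 0.2)),
            ("CB", (-5.3, 2.8, 0.4)),
        ]
    ),
    "PHE": _ring_template(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")),
    "TYR": _ring_template(
        ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), extra=(("OH", (0.0, 2.8, 0.0)),)
    ),
    "HIS": _ring_template(("CG", "ND1", "CE1", "NE2", "CD2"), radius=1.17),
}


def rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Right-handed rotation about an arbitrary axis (Rodrigues form)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


@dataclass(frozen=True)
class ResiduePlacement:
    resname: str
    chain: str
    resnum: int
    anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float, float] | None = None  # axis xyz + deg

    def transform(self) -> np.ndarray:
        if self.rotation is None:
            return np.eye(3)
        ax, ay, az, deg = self.rotation
        return rotation_matrix((ax, ay, az), deg)


@dataclass(frozen=True)
class ToyComplexSpec:
    placements: tuple[ResiduePlacement, ...]
    n_frames: int = 1
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        for p in self.placements:
            if p.resname not in RESIDUE_TEMPLATES:
                raise ParameterError(f"no template for residue {p.resname!r}")


def _element_from_name(name: str) -> str:
    return name.lstrip("0123456789")[0].upper()


def generate_toy_complex(
    spec: ToyComplexSpec, system_id: str = "toy"
) -> tuple[Topology, Trajectory]:
    """Build a two-chain toy complex and its jittered frame ensemble.

    Base coordinates place each residue's anchor site exactly as specified;
    any inter-atom clash below 1 Å in the base placement raises a
    generation error before frames are drawn.
    """
    atoms: list[Atom] = []
    for placement in sorted(spec.placements, key=lambda p: (p.chain, p.resnum)):
        rot = placement.transform()
        anchor = np.asarray(placement.anchor, float)
        rk = ResidueKey(placement.chain, placement.resnum, placement.resname)
        for name, local in RESIDUE_TEMPLATES[placement.resname]:
            coords = rot @ np.asarray(local, float) + anchor
            atoms.append(
                Atom(
                    atom_name=name,
                    element=_element_from_name(name),
                    residue_key=rk,
                    is_sidechain=name not in BACKBONE_ATOM_NAMES,
                    coords=tuple(float(v) for v in coords),
                )
            )
    base = np.asarray([a.coords for a in atoms], float)
    if len(atoms) >= 2:
        deltas = base[:, None, :] - base[None, :, :]
        dist = np.sqrt((deltas**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1.0:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            raise GenerationError(
                f"atoms {atoms[i].atom_name}/{atoms[j].atom_name} overlap "
                f"({dist.min():.2f} Å)"
            )

    # receptor chain = chain of the first placement, Gα = the second chain seen
    chains = list(dict.fromkeys(p.chain for p in spec.placements))
    selections = {}
    if len(chains) >= 2:
        selections = {
            "gpcr": frozenset(a.residue_key for a in atoms if a.residue_key.chain == chains[0]),
            "galpha": frozenset(a.residue_key for a in atoms if a.residue_key.chain == chains[1]),
        }
    topology = Topology(atoms=atoms, selections=selections)

    rng = np.random.default_rng(spec.seed)
    frames = [
        base + (rng.normal(0.0, spec.jitter, base.shape) if spec.jitter > 0 else 0.0)
        for _ in range(spec.n_frames)
    ]
    trajectory = Trajectory(
        topology=topology,
        frames=[np.asarray(f, float) for f in frames],
        frame_ids=list(range(spec.n_frames)),
        system_id=system_id,
    )
    return topology, trajectory


def face_to_face(
    resname_a: str,
    resname_b: str,
    distance: float,
    chain_a: str = "R",
    chain_b: str = "A",
    n_frames: int = 1,
    jitter: float = 0.0,
    seed: int = 0,
) -> ToyComplexSpec:
    """Two residues whose anchor sites face each other ``distance`` Å apart."""
    return ToyComplexSpec(
        placements=(
            ResiduePlacement(resname_a, chain_a, 1),
            ResiduePlacement(
                resname_b, chain_b, 1, anchor=(distance, 0.0, 0.0), rotation=(0, 0, 1, 180)
            ),
        ),
        n_frames=n_frames,
        jitter=jitter,
        seed=seed,
    )


def write_multi_model_pdb(
    topology: Topology, frames: Sequence[np.ndarray], path: str | Path
) -> None:
    """Emit a multi-model PDB (one MODEL per frame) for the toy readers."""
    lines: list[str] = []
    for m, coords in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        prev_chain = None
        for atom, (x, y, z) in zip(topology.atoms, coords):
            if prev_chain is not None and atom.residue_key.chain != prev_chain:
                lines.append("TER")
            prev_chain = atom.residue_key.chain
            name = atom.atom_name
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_field:4s} {atom.residue_key.resname:>3s} "
                f"{atom.residue_key.chain}{atom.residue_key.resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}"
            )
            serial += 1
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
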