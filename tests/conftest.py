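"""Shared fixtures: toy complexes, numbering maps, planted fingerprints."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrcontacts.annotation_io import (
    GPCR_SIDE,
    GPROT_SIDE,
    MapEntry,
    NumberingMap,
    Topology,
)
from gpcrcontacts.synthetic import PlantedSpec, generate_fingerprints


def toy_numbering_map(
    topology: Topology,
    gpcr_generics: dict[int, tuple[str, str]] | None = None,
    gprot_generics: dict[int, tuple[str, str]] | None = None,
) -> NumberingMap:
    """Assign generic numbers to a toy two-chain complex.

    Defaults number receptor residues 3x50, 3x51, ... (TM3) and Gα residues
    G.H5.10, G.H5.11, ... (H5) in residue order; explicit per-resnum
    (generic, sse) overrides may be given.
    """
    entries: dict[tuple[str, int], MapEntry] = {}
    for i, rk in enumerate(topology.residues("gpcr")):
        generic, sse = (gpcr_generics or {}).get(rk.resnum, (f"3x{50 + i}", "TM3"))
        entries[(rk.chain, rk.resnum)] = MapEntry(generic, sse, GPCR_SIDE)
    for i, rk in enumerate(topology.residues("galpha")):
        generic, sse = (gprot_generics or {}).get(rk.resnum, (f"G.H5.{10 + i}", "H5"))
        entries[(rk.chain, rk.resnum)] = MapEntry(generic, sse, GPROT_SIDE)
    return NumberingMap(entries)


#: Near-separable planted occupancies: class-specific contacts almost always
#: present in their own class and almost never elsewhere, while keeping
#: nonzero within-class variance in every feature.
SEPARABLE_SPEC = dict(
    p_specific_own=0.98, p_specific_other=0.02, p_background=0.05
)


@pytest.fixture(scope="session")
def planted_default():
    return generate_fingerprints(PlantedSpec(seed=20240501))


@pytest.fixture(scope="session")
def planted_separable():
    return generate_fingerprints(PlantedSpec(seed=20240502, **SEPARABLE_SPEC))
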