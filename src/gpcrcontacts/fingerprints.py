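"""Binary interaction fingerprints, contact frequencies, and the
persistence taxonomy (subfamily-specific vs common contacts).

A contact pair is keyed by its generic numbers, e.g. ``"3x53:G.H5.19"``.
Fingerprints are frames × pairs binary matrices; per-system frequencies are
column means; a pair is *persistent* in a Gα class when its frequency
exceeds the threshold (default 20%, strict) in at least one of that class's
systems. Pairs persistent in exactly one class are subfamily-specific,
pairs persistent in all three are common.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GPCR_SIDE, GPROT_SIDE, NumberingMap
from .contact_detection import ContactTimeline
from .errors import ConfigurationError, DataError, ValidationError

CLASSES = ("Gs", "Gi", "Gq")

LABEL_COMMON = "common"
LABEL_OTHER = "other"


def pair_key(gpcr_generic: str, gprot_generic: str) -> str:
    return f"{gpcr_generic}:{gprot_generic}"


def split_pair_key(key: str) -> tuple[str, str]:
    gpcr, _, gprot = key.partition(":")
    if not gpcr or not gprot:
        raise ValidationError(f"malformed pair key {key!r}")
    return gpcr, gprot


@dataclass
class FingerprintMatrix:
    """Frames × contact-pairs binary matrix with per-row system/class labels."""

    pairs: list[str]
    data: np.ndarray  # (n_rows, n_pairs) uint8
    system_ids: np.ndarray  # object, per row
    class_labels: np.ndarray  # object, per row
    frame_ids: np.ndarray  # int, per row (within-system frame id)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.pairs):
            raise ValidationError("fingerprint data shape does not match pair list")
        if not np.isin(self.data, (0, 1)).all():
            raise ValidationError("fingerprint entries must be 0/1")
        n = self.data.shape[0]
        for name in ("system_ids", "class_labels", "frame_ids"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match row count")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def systems(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.system_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def system_block(self, system_id: str) -> np.ndarray:
        mask = np.asarray([s == system_id for s in self.system_ids])
        return self.data[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.pairs)
        df.insert(0, "frame_id", self.frame_ids)
        df.insert(0, "class_label", self.class_labels)
        df.insert(0, "system_id", self.system_ids)
        return df

    def system_to_class(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for s, c in zip(self.system_ids, self.class_labels):
            prev = mapping.setdefault(str(s), str(c))
            if prev != str(c):
                raise ValidationError(f"system {s} carries conflicting class labels")
        return mapping


def concat_matrices(blocks: Sequence[FingerprintMatrix]) -> FingerprintMatrix:
    if not blocks:
        raise DataError("no fingerprint blocks to concatenate")
    pairs = blocks[0].pairs
    for b in blocks[1:]:
        if b.pairs != pairs:
            raise ValidationError("fingerprint blocks have different pair universes")
    return FingerprintMatrix(
        pairs=list(pairs),
        data=np.vstack([b.data for b in blocks]),
        system_ids=np.concatenate([b.system_ids for b in blocks]),
        class_labels=np.concatenate([b.class_labels for b in blocks]),
        frame_ids=np.concatenate([b.frame_ids for b in blocks]),
    )


# ---------------------------------------------------------------------------
# Universe construction and encoding
# ---------------------------------------------------------------------------

def build_pair_universe(
    timelines: Sequence[ContactTimeline],
    resolved_regions: Mapping[str, set[str]] | None = None,
    resolved_gprot_regions: Mapping[str, set[str]] | None = None,
) -> list[str]:
    """Union of observed contact pairs, region-filtered, lexicographic.

    ``resolved_regions`` maps system id → the GPCR generic positions that
    are structurally resolved in that system; pairs whose receptor-side
    position is missing from any system are dropped, so the feature set is
    comparable across complexes. Gα-side filtering is available through
    ``resolved_gprot_regions`` but off by default.
    """
    if not timelines:
        raise DataError("no timelines given")
    universe: set[str] = set()
    for tl in timelines:
        for e in tl.events:
            universe.add(pair_key(e.gpcr_generic, e.gprot_generic))
    if resolved_regions is not None:
        keep_gpcr = set.intersection(*(set(v) for v in resolved_regions.values()))
        universe = {k for k in universe if split_pair_key(k)[0] in keep_gpcr}
    if resolved_gprot_regions is not None:
        keep_gprot = set.intersection(*(set(v) for v in resolved_gprot_regions.values()))
        universe = {k for k in universe if split_pair_key(k)[1] in keep_gprot}
    if not universe:
        raise DataError("pair universe is empty after region filtering")
    return sorted(universe)


def encode(timeline: ContactTimeline, pair_universe: Sequence[str]) -> np.ndarray:
    """One-hot encode a timeline: entry (f, p) = 1 iff pair p occurs in frame f.

    Contact types collapse to a single binary event at the pair level;
    pairs outside the universe are dropped.
    """
    if timeline.n_frames < 1:
        raise DataError("timeline has no frames")
    col = {p: j for j, p in enumerate(pair_universe)}
    block = np.zeros((timeline.n_frames, len(pair_universe)), dtype=np.uint8)
    for e in timeline.events:
        j = col.get(pair_key(e.gpcr_generic, e.gprot_generic))
        if j is not None:
            block[e.frame_id, j] = 1
    return block


def build_fingerprint_matrix(
    timelines: Sequence[ContactTimeline],
    pair_universe: Sequence[str],
    system_to_class: Mapping[str, str],
) -> FingerprintMatrix:
    blocks = []
    for tl in timelines:
        data = encode(tl, pair_universe)
        cls = system_to_class.get(tl.system_id, LABEL_OTHER)
        blocks.append(
            FingerprintMatrix(
                pairs=list(pair_universe),
                data=data,
                system_ids=np.asarray([tl.system_id] * tl.n_frames, dtype=object),
                class_labels=np.asarray([cls] * tl.n_frames, dtype=object),
                frame_ids=np.arange(tl.n_frames),
            )
        )
    return concat_matrices(blocks)


def frequencies(matrix: FingerprintMatrix) -> pd.DataFrame:
    """Per-system contact frequencies: fraction of frames with each contact."""
    rows = {}
    for system in matrix.systems():
        block = matrix.system_block(system)
        if block.shape[0] == 0:
            raise DataError(f"system {system} has no fingerprint rows")
        rows[system] = block.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.pairs)


# ---------------------------------------------------------------------------
# Persistence taxonomy
# ---------------------------------------------------------------------------

@dataclass
class PersistenceLabels:
    """Partition of the pair universe into specific/common/other."""

    labels: pd.DataFrame  # index pair key; columns: label, sublabel, per-class bool
    threshold: float

    def label_of(self, pair: str) -> str:
        return str(self.labels.loc[pair, "label"])

    def pairs_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels["label"] == label])

    def persistent_in(self, pair: str) -> frozenset[str]:
        row = self.labels.loc[pair]
        return frozenset(c for c in CLASSES if bool(row[f"persistent_{c}"]))


def classify_persistence(
    freq_table: pd.DataFrame,
    system_to_class: Mapping[str, str],
    threshold: float = 0.20,
) -> PersistenceLabels:
    """Label each contact pair by where it persists (>threshold, strict).

    specific-X: persistent in exactly class X; common: persistent in all of
    Gs/Gi/Gq; other: persistent in exactly two classes (sublabel ``dual``)
    or in none (sublabel ``never``).
    """
    systems_by_class: dict[str, list[str]] = {c: [] for c in CLASSES}
    for system in freq_table.index:
        cls = system_to_class.get(str(system))
        if cls in systems_by_class:
            systems_by_class[cls].append(str(system))
    for cls, systems in systems_by_class.items():
        if not systems:
            raise ConfigurationError(f"class {cls} has no systems in the table")

    records = []
    for pair in freq_table.columns:
        persistent = {
            cls: bool((freq_table.loc[systems, pair] > threshold).any())
            for cls, systems in systems_by_class.items()
        }
        pclasses = frozenset(c for c, flag in persistent.items() if flag)
        if len(pclasses) == 3:
            label, sublabel = LABEL_COMMON, ""
        elif len(pclasses) == 1:
            label, sublabel = f"specific-{next(iter(pclasses))}", ""
        elif len(pclasses) == 2:
            label, sublabel = LABEL_OTHER, "dual"
        else:
            label, sublabel = LABEL_OTHER, "never"
        records.append(
            {
                "pair_key": pair,
                "label": label,
                "sublabel": sublabel,
                **{f"persistent_{c}": persistent[c] for c in CLASSES},
            }
        )
    df = pd.DataFrame.from_records(records).set_index("pair_key")
    return PersistenceLabels(labels=df, threshold=threshold)


# ---------------------------------------------------------------------------
# Composition statistics and subset means
# ---------------------------------------------------------------------------

def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sse_composition(
    pairs: Iterable[str],
    numbering_map: NumberingMap,
    side: str,
) -> dict[str, float]:
    """Percentage of contact pairs per secondary structural element.

    ``side`` selects the receptor (``GPCR``) or Gα (``GPROT``) half of each
    pair key; percentages are rounded half-up to one decimal and sum to 100
    within rounding error.
    """
    if side not in (GPCR_SIDE, GPROT_SIDE):
        raise ValidationError(f"side must be GPCR or GPROT, got {side!r}")
    pairs = list(pairs)
    if not pairs:
        raise DataError("no pairs to summarize")
    counts: dict[str, int] = {}
    for key in pairs:
        generic = split_pair_key(key)[0 if side == GPCR_SIDE else 1]
        sse = numbering_map.sse_of_generic(generic, side)
        if sse is None:
            raise ValidationError(f"generic {generic!r} has no SSE on side {side}")
        counts[sse] = counts.get(sse, 0) + 1
    total = len(pairs)
    return {sse: _round_half_up(100.0 * c / total) for sse, c in sorted(counts.items())}


def mean_frequency_over_subset(
    freq_table: pd.DataFrame,
    system_id: str,
    subset: Iterable[str],
) -> float:
    """Mean contact frequency of one system over a subset of pairs."""
    cols = [p for p in subset if p in freq_table.columns]
    if not cols:
        raise DataError("subset does not intersect the pair universe")
    return float(freq_table.loc[system_id, cols].mean())
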