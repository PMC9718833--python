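"""Weighted G protein coupling promiscuity index.

Three coupling datasets are harmonized into categorical per-subfamily
scores (primary = 1, secondary = 0.5, none = 0). A receptor's per-dataset
index is the mean score over the four Gα subfamilies (Gs, Gi, Gq, G12/13);
the composite promiscuity index averages the weighted per-dataset indices,
with weights reflecting how directly each dataset measures coupling:
direct BRET G protein activation (AVET) ×4, literature curation (GTP,
Guide to Pharmacology) ×2, chimeric-G-protein assay (INOUE) ×1. The
composite is therefore bounded by [0, 4].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    COUPLING_CATEGORIES,
    DATASET_IDS,
    SUBFAMILIES,
    CouplingTable,
)
from .errors import ValidationError

log = logging.getLogger(__name__)

DATASET_WEIGHTS: Mapping[str, float] = {"AVET": 4.0, "GTP": 2.0, "INOUE": 1.0}

CATEGORY_SCORES: Mapping[str, float] = {"primary": 1.0, "secondary": 0.5, "none": 0.0}


def categorize_emax(emax: float) -> str:
    """Map a double-normalized Emax to a coupling category.

    Strictly >0.8 is primary, strictly between 0.2 and 0.8 is secondary,
    anything else (including the 0.2/0.8 boundaries) is none. Negative
    values are treated as non-coupling with a warning.
    """
    if not np.isfinite(emax):
        raise ValidationError("Emax must be finite")
    if emax < 0:
        warnings.warn(f"negative Emax {emax}; treated as non-coupler", stacklevel=2)
        return "none"
    if emax > 0.8:
        return "primary"
    if emax > 0.2:
        return "secondary"  # boundary 0.8 falls here (lower category)
    return "none"  # boundary 0.2 falls here


def dataset_index(scores: Mapping[str, str]) -> float:
    """Mean numeric coupling score over the four Gα subfamilies.

    ``scores`` maps subfamily → category; subfamilies a dataset never
    measured count as 0 (logged), keeping the four-subfamily denominator.
    """
    total = 0.0
    for sub in SUBFAMILIES:
        cat = scores.get(sub)
        if cat is None:
            log.debug("subfamily %s missing; scored 0", sub)
            continue
        if cat not in CATEGORY_SCORES:
            raise ValidationError(f"unknown category {cat!r}")
        total += CATEGORY_SCORES[cat]
    return total / len(SUBFAMILIES)


@dataclass
class PromiscuityIndex:
    receptor: str
    dataset_indices: dict[str, float]  # dataset id -> unweighted mean, present only
    composite: float

    @property
    def n_datasets_present(self) -> int:
        return len(self.dataset_indices)


def promiscuity_index(
    receptor: str,
    per_dataset: Mapping[str, float],
    include_missing_as_zero: bool = False,
) -> PromiscuityIndex:
    """Composite index: mean over datasets of weight × per-dataset index.

    By default only datasets that measured the receptor enter the mean;
    ``include_missing_as_zero`` instead counts absent datasets as 0 over
    the full three-dataset denominator.
    """
    present = {d: v for d, v in per_dataset.items() if d in DATASET_IDS}
    unknown = set(per_dataset) - set(present)
    if unknown:
        raise ValidationError(f"unknown dataset ids {sorted(unknown)}")
    if not present:
        raise ValidationError(f"receptor {receptor} absent from every dataset")
    weighted = [DATASET_WEIGHTS[d] * v for d, v in present.items()]
    denom = len(DATASET_IDS) if include_missing_as_zero else len(weighted)
    composite = float(sum(weighted) / denom)
    return PromiscuityIndex(
        receptor=receptor,
        dataset_indices=dict(present),
        composite=composite,
    )


def _table_scores(table: CouplingTable) -> dict[str, dict[str, str]]:
    """receptor → subfamily → category, categorizing Emax records on the fly."""
    out: dict[str, dict[str, str]] = {}
    for rec in table.records:
        cat = rec.category if rec.category is not None else categorize_emax(rec.emax)
        out.setdefault(rec.receptor, {})[rec.subfamily] = cat
    return out


def compute_promiscuity(
    tables: Sequence[CouplingTable],
    include_missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Promiscuity indices for every receptor seen in any dataset.

    Returns a table with one row per receptor: the unweighted per-dataset
    indices (NaN when absent), the composite, and the dataset count,
    sorted by descending composite then receptor name so ranking is
    independent of input order.
    """
    by_dataset = {t.dataset_id: _table_scores(t) for t in tables}
    receptors = sorted({r for scores in by_dataset.values() for r in scores})
    rows = []
    for receptor in receptors:
        per_dataset = {
            d: dataset_index(scores[receptor])
            for d, scores in by_dataset.items()
            if receptor in scores
        }
        idx = promiscuity_index(receptor, per_dataset, include_missing_as_zero)
        rows.append(
            {
                "receptor": receptor,
                "idx_avet": per_dataset.get("AVET", np.nan),
                "idx_gtp": per_dataset.get("GTP", np.nan),
                "idx_inoue": per_dataset.get("INOUE", np.nan),
                "composite": idx.composite,
                "n_datasets": idx.n_datasets_present,
            }
        )
    df = pd.DataFrame.from_records(rows)
    return df.sort_values(["composite", "receptor"], ascending=[False, True]).reset_index(
        drop=True
    )
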