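"""End-to-end orchestration: detect → fingerprint → persist → LDA → code.

A run is described by a TOML config listing the systems (topology,
trajectory files, frame window, numbering map, Gα class) plus the analysis
parameters (criteria overrides, persistence threshold, code size k, split
fraction, seed). All artifacts land in one output directory together with
a manifest that records versions, seeds, criteria and the counts entering
and leaving every filter stage, so every number in the report is traceable.
"""

from __future__ import annotations

import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import (
    GPCR_SIDE,
    read_numbering_map,
    read_topology,
    read_trajectory,
    write_fingerprint_tsv,
    write_frequency_tsv,
    write_timeline_tsv,
)
from .contact_detection import ContactCriteria, detect_contacts
from .errors import ConfigurationError, GpcrContactsError
from .fingerprints import (
    CLASSES,
    build_fingerprint_matrix,
    build_pair_universe,
    classify_persistence,
    frequencies,
)
from .selectivity_code import (
    class_mean_frequencies,
    composite_scores,
    extract_code,
    fit_lda,
    holdout_accuracy,
)

log = logging.getLogger(__name__)


@dataclass
class SystemConfig:
    system_id: str
    class_label: str
    topology: Path
    trajectories: list[Path]
    numbering_map: Path
    gpcr_chain: str
    galpha_chain: str
    frame_window: tuple[int, int] | None = None


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    out_dir: Path
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    threshold: float = 0.20
    k: int = 10
    split: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        classes = {s.class_label for s in self.systems}
        missing = set(CLASSES) - classes
        if missing:
            raise ConfigurationError(
                f"code derivation needs systems for all of {CLASSES}; missing {sorted(missing)}"
            )
        for s in self.systems:
            for p in [s.topology, s.numbering_map, *s.trajectories]:
                if not Path(p).exists():
                    raise ConfigurationError(f"path {p} does not exist")


def criteria_from_dict(d: dict) -> ContactCriteria:
    kwargs = dict(d)
    if "vdw_radii" in kwargs:
        kwargs["vdw_radii"] = {k.upper(): float(v) for k, v in kwargs["vdw_radii"].items()}
    return ContactCriteria(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    base = Path(path).parent
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    systems = [
        SystemConfig(
            system_id=str(s["id"]),
            class_label=str(s["class"]),
            topology=base / s["topology"],
            trajectories=[base / t for t in s.get("trajectories", [s["topology"]])],
            numbering_map=base / s["map"],
            gpcr_chain=str(s.get("gpcr_chain", "R")),
            galpha_chain=str(s.get("galpha_chain", "A")),
            frame_window=tuple(s["frame_window"]) if "frame_window" in s else None,
        )
        for s in raw.get("systems", [])
    ]
    return RunConfig(
        systems=systems,
        out_dir=base / raw.get("out_dir", "out"),
        criteria=criteria_from_dict(raw.get("criteria", {})),
        threshold=float(raw.get("threshold", 0.20)),
        k=int(raw.get("k", 10)),
        split=float(raw.get("split", 0.8)),
        seed=int(raw.get("seed", 0)),
    )


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Stage errors abort the run with a stage-tagged diagnostic and leave a
    ``STALE`` marker next to whatever partial outputs exist.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "k": config.k,
        "split": config.split,
        "criteria": {
            "salt_bridge_cutoff": config.criteria.salt_bridge_cutoff,
            "hbond_da_cutoff": config.criteria.hbond_da_cutoff,
            "hbond_angle_max": config.criteria.hbond_angle_max,
            "vdw_slack": config.criteria.vdw_slack,
            "pistack_centroid_cutoff": config.criteria.pistack_centroid_cutoff,
            "pistack_angle_max": config.criteria.pistack_angle_max,
            "catpi_cutoff": config.criteria.catpi_cutoff,
            "catpi_angle_max": config.criteria.catpi_angle_max,
            "his_cation": config.criteria.his_cation,
        },
        "stages": {},
        "artifacts": {},
    }
    stage = "setup"
    t0 = time.time()
    try:
        # --- detection ----------------------------------------------------
        stage = "detect"
        timelines = []
        resolved: dict[str, set[str]] = {}
        system_to_class: dict[str, str] = {}
        timeline_paths = []
        for s in config.systems:
            topo = read_topology(s.topology, gpcr_chain=s.gpcr_chain, galpha_chain=s.galpha_chain)
            traj = read_trajectory(
                s.trajectories, topo, frame_range=s.frame_window, system_id=s.system_id
            )
            nmap = read_numbering_map(s.numbering_map)
            tl = detect_contacts(traj, nmap, criteria=config.criteria)
            timelines.append(tl)
            resolved[s.system_id] = nmap.generics(GPCR_SIDE)
            system_to_class[s.system_id] = s.class_label
            tl_path = out / f"timeline_{s.system_id}.tsv"
            write_timeline_tsv(tl, tl_path)
            timeline_paths.append(str(tl_path))
            manifest["stages"].setdefault("detect", {})[s.system_id] = {
                "n_frames": tl.n_frames,
                "n_events": len(tl.events),
                "hbond_mode": tl.metadata.get("hbond_mode"),
                "unmapped_residues": tl.metadata.get("unmapped_gpcr_residues", 0)
                + tl.metadata.get("unmapped_gprot_residues", 0),
            }
        manifest["artifacts"]["timelines"] = timeline_paths

        # --- universe + fingerprints -------------------------------------
        stage = "fingerprint"
        observed = {
            f"{e.gpcr_generic}:{e.gprot_generic}" for tl in timelines for e in tl.events
        }
        universe = build_pair_universe(timelines, resolved_regions=resolved)
        matrix = build_fingerprint_matrix(timelines, universe, system_to_class)
        fp_path = out / "fingerprints.tsv"
        write_fingerprint_tsv(matrix, fp_path)
        manifest["artifacts"]["fingerprints"] = str(fp_path)
        manifest["stages"]["fingerprint"] = {
            "n_observed_pairs": len(observed),
            "n_universe_pairs": len(universe),
            "n_region_filtered": len(observed) - len(universe),
            "n_rows": matrix.n_rows,
        }

        # --- frequencies + persistence ------------------------------------
        stage = "persist"
        freq = frequencies(matrix)
        freq_path = out / "frequencies.tsv"
        write_frequency_tsv(freq, freq_path)
        manifest["artifacts"]["frequencies"] = str(freq_path)
        labels = classify_persistence(freq, system_to_class, threshold=config.threshold)
        labels_path = out / "persistence.tsv"
        labels.labels.to_csv(labels_path, sep="\t")
        manifest["artifacts"]["persistence"] = str(labels_path)
        counts = labels.labels["label"].value_counts().to_dict()
        manifest["stages"]["persist"] = {"label_counts": {k: int(v) for k, v in counts.items()}}

        # --- LDA + code ----------------------------------------------------
        stage = "lda"
        model = fit_lda(matrix)
        model_path = out / "model.json"
        model.to_json(model_path)
        manifest["artifacts"]["model"] = str(model_path)
        accuracy = holdout_accuracy(matrix, split=config.split, seed=config.seed)
        freq_by_class = class_mean_frequencies(freq, system_to_class)
        scores = composite_scores(model, freq_by_class)
        k = min(config.k, len(universe))
        if k < config.k:
            log.info("k clamped from %d to universe size %d", config.k, k)
        code = extract_code(scores, k=k, persistence=labels)
        code_path = out / "code.tsv"
        code.to_csv(code_path, sep="\t", index=False)
        manifest["artifacts"]["code"] = str(code_path)
        manifest["stages"]["lda"] = {
            "holdout_accuracy": accuracy,
            "explained_variance_ratio": model.explained_variance_ratio.tolist(),
            "k_used": k,
        }

        # --- report --------------------------------------------------------
        stage = "report"
        report_path = out / "report.tsv"
        report_rows = [
            {"quantity": "n_universe_pairs", "value": len(universe)},
            {"quantity": "n_fingerprint_rows", "value": matrix.n_rows},
            *[
                {"quantity": f"n_{label}", "value": int(n)}
                for label, n in sorted(counts.items())
            ],
            {"quantity": "holdout_accuracy", "value": accuracy},
            {
                "quantity": "explained_variance_component1",
                "value": float(model.explained_variance_ratio[0]),
            },
            {
                "quantity": "explained_variance_component2",
                "value": float(model.explained_variance_ratio[1]),
            },
        ]
        pd.DataFrame(report_rows).to_csv(report_path, sep="\t", index=False)
        manifest["artifacts"]["report"] = str(report_path)
        summary_path = out / "summary.txt"
        summary_path.write_text(
            "\n".join(f"{r['quantity']}\t{r['value']}" for r in report_rows) + "\n"
        )
        manifest["artifacts"]["summary"] = str(summary_path)

        manifest["elapsed_s"] = round(time.time() - t0, 3)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except GpcrContactsError as exc:
        (out / "STALE").write_text(
            f"run aborted during stage {stage!r}: {exc}\npartial outputs are stale\n"
        )
        raise GpcrContactsError(f"[{stage}] {exc}") from exc
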