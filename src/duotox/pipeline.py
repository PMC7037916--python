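"""End-to-end orchestration: data -> composite -> alignment -> fields -> PLS
-> validation -> contours -> screening, driven by one serializable config.

A run writes its bundle atomically (into ``<out_dir>.partial`` first, renamed
on success) and is reproducible bit-for-bit from the same config and seed.
The single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import composite as ci
from . import dataset as ds
from . import design
from . import fields as fl
from . import prepare as prep
from . import qsar
from . import synthetic as syn
from .errors import InputError, UsageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    mode: str = "synthetic"  # "synthetic" or "structures"
    out_dir: str = "duotox_run"
    log_level: str = "INFO"
    # synthetic mode
    synthetic: dict = dc_field(default_factory=dict)  # SyntheticSpec kwargs (seed injected)
    # structures mode
    toxicity_table: str = "fixture"  # "fixture" or a CSV path
    structures_path: str | None = None
    structures_format: str | None = None
    resplit_n_test: int | None = None  # optional seeded re-randomized split
    # stage settings
    composite: dict = dc_field(
        default_factory=lambda: {"weight_algae": 0.8, "weight_geno": 0.2, "calibration": ci.MODE_SHARED}
    )
    prep: dict = dc_field(default_factory=dict)  # PrepConfig kwargs
    fields: dict = dc_field(default_factory=dict)  # FieldConfig kwargs
    pls: dict = dc_field(
        default_factory=lambda: {
            "components": "auto",
            "max_components": qsar.MAX_COMPONENTS,
            "criterion": "q2",
            "scramble": True,
            "scramble_repeats": 20,
        }
    )
    contours: dict = dc_field(default_factory=lambda: {"favored_pct": 80.0, "disfavored_pct": 20.0})
    screen: dict = dc_field(default_factory=dict)  # {"parent_id": ..., "candidates_csv": ...}

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "structures"):
            raise UsageError("mode must be 'synthetic' or 'structures'")
        if self.mode == "structures" and self.toxicity_table != "fixture" and not self.toxicity_table:
            raise UsageError("structures mode needs a toxicity table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run and return the path of the output bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_synth = int(seeds[0].generate_state(1)[0])
    seed_scramble = int(seeds[1].generate_state(1)[0])
    seed_resplit = int(seeds[2].generate_state(1)[0])

    out_dir = Path(config.out_dir)
    work = Path(str(out_dir) + ".partial")
    if work.exists():
        shutil.rmtree(work)
    work.mkdir(parents=True)
    (work / "contours").mkdir()
    log_lines: list[dict] = []

    def stage(name: str, **info) -> None:
        entry = {"stage": name, **info}
        log_lines.append(entry)
        logger.info("%s", entry)

    field_config = fl.FieldConfig(**config.fields)

    if config.mode == "synthetic":
        spec = syn.SyntheticSpec(**{"seed": seed_synth, **config.synthetic})
        molecules = syn.generate_molecule_set(spec)
        activities = syn.plant_activities(molecules, spec, field_config)
        descriptors = activities.descriptors
        y_all = activities.z
        # deterministic 80/20 split by index hash for reproducibility
        rng = np.random.default_rng(seed_resplit)
        n = len(molecules)
        test_rows = np.sort(rng.choice(n, size=max(2, n // 5), replace=False))
        train_rows = np.setdiff1d(np.arange(n), test_rows)
        composite_summary = None
        stage("synthetic", n_molecules=n, descriptor_digest=_digest(descriptors.X))
    else:
        if config.toxicity_table == "fixture":
            data = ds.load_table1_fixture()
        else:
            data = ds.read_toxicity_table(config.toxicity_table)
        if config.resplit_n_test:
            data = ds.resplit(data, config.resplit_n_test, seed_resplit)
        comp_cfg = ci.calibrate_standard(
            data.records,
            mode=config.composite.get("calibration", ci.MODE_SHARED),
            weight_algae=config.composite.get("weight_algae", 0.8),
            weight_geno=config.composite.get("weight_geno", 0.2),
        )
        table = ci.composite_table(data, comp_cfg)
        composite_summary = ci.reproduction_summary(table)
        table.to_csv(work / "composite_table.csv", index=False)
        stage("composite", **composite_summary)

        if not config.structures_path:
            raise InputError("structures mode requires structures_path")
        raw_mols = ds.read_structures(config.structures_path, config.structures_format)
        prep_cfg = prep.PrepConfig(**config.prep)
        modeled = [r for r in data.records if r.compound_id in raw_mols]
        if not modeled:
            raise InputError("no toxicity record has a matching structure")
        prepared = {
            r.compound_id: prep.prepare_3d(raw_mols[r.compound_id], prep_cfg, r.compound_id)
            for r in modeled
        }
        template = prepared.get(prep_cfg.template_id)
        if template is None:
            raise InputError(f"template {prep_cfg.template_id} has no structure")
        molecules = [
            m if m.compound_id == template.compound_id else prep.align_to_template(m, template, prep_cfg)
            for m in prepared.values()
        ]
        prep.write_aligned_sdf(molecules, work / "aligned.sdf")
        stage("prepare_align", n_molecules=len(molecules))

        descriptors = fl.assemble_descriptors(molecules, field_config)
        y_map = {m.compound_id: ci.compute_composite(data.get(m.compound_id), comp_cfg).z for m in molecules}
        y_all = np.array([y_map[m] for m in descriptors.molecule_ids])
        splits = {r.compound_id: r.split for r in modeled}
        train_rows = np.array(
            [i for i, cid in enumerate(descriptors.molecule_ids) if splits[cid] != "test"]
        )
        test_rows = np.array(
            [i for i, cid in enumerate(descriptors.molecule_ids) if splits[cid] == "test"]
        )
        stage("fields", descriptor_digest=_digest(descriptors.X), n_columns=descriptors.X.shape[1])

    components = config.pls.get("components", "auto")
    report = qsar.build_model_report(
        descriptors,
        y_train=y_all[train_rows],
        train_rows=train_rows,
        test_rows=test_rows if len(test_rows) >= 2 else None,
        y_test=y_all[test_rows] if len(test_rows) >= 2 else None,
        n_components=None if components == "auto" else int(components),
        max_components=int(config.pls.get("max_components", qsar.MAX_COMPONENTS)),
        criterion=config.pls.get("criterion", "q2"),
    )
    stage("pls", n_components=report.n_components, q2=report.q2, r2=report.r2)

    scrambling_dict = None
    if config.pls.get("scramble", True):
        scr = qsar.progressive_scrambling(
            descriptors.X[train_rows],
            y_all[train_rows],
            report.n_components,
            seed=seed_scramble,
            n_repeats=int(config.pls.get("scramble_repeats", 20)),
        )
        scrambling_dict = {
            "q2_scr": scr.q2_scr,
            "csdep": scr.csdep,
            "slope": scr.slope,
            "critical_r2yy": scr.critical_r2yy,
            "baseline_q2": scr.baseline_q2,
            "levels": scr.levels,
        }
        stage("scrambling", slope=scr.slope, q2_scr=scr.q2_scr)

    contours = qsar.extract_contours(
        report.model,
        descriptors,
        favored_pct=float(config.contours.get("favored_pct", 80.0)),
        disfavored_pct=float(config.contours.get("disfavored_pct", 20.0)),
    )
    for name in prep.FIELD_NAMES:
        fl.write_cube(
            contours.grid,
            contours.stdev_coeff[name],
            work / "contours" / f"stdev_coeff_{name}.cube",
            comment=f"StDev*Coeff field {name}",
        )
    stage("contours", favored_cells={n: int(m.sum()) for n, m in contours.favored.items()})

    screening = None
    if config.screen.get("parent_id") and config.screen.get("candidates_csv"):
        import pandas as pd

        cand = pd.read_csv(config.screen["candidates_csv"])
        parent_id = config.screen["parent_id"]
        parent_row = cand[cand["compound_id"] == parent_id]
        if parent_row.empty:
            raise InputError(f"candidates table has no parent row {parent_id}")
        candidates = [
            (str(r.compound_id), float(r.composite))
            for r in cand.itertuples()
            if str(r.compound_id) != parent_id
        ]
        reports = design.screen_derivatives(parent_id, float(parent_row.iloc[0]["composite"]), candidates)
        screening = [dataclasses.asdict(r) for r in reports]
        stage("screening", ranking=[r.derivative_id for r in reports])

    bundle = {
        "config": config.to_dict(),
        "seeds": {"synthetic": seed_synth, "scrambling": seed_scramble, "resplit": seed_resplit},
        "composite_summary": composite_summary,
        "model_report": report.to_dict(),
        "scrambling_report": scrambling_dict,
        "screening_report": screening,
    }
    (work / "model_report.json").write_text(
        json.dumps(bundle, indent=2, default=_json_default, sort_keys=True)
    )
    (work / "log.jsonl").write_text(
        "\n".join(json.dumps(e, default=_json_default) for e in log_lines) + "\n"
    )
    if out_dir.exists():
        shutil.rmtree(out_dir)
    os.replace(work, out_dir)
    return out_dir
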