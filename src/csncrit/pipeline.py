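"""End-to-end orchestration: curate -> similarity -> sweep -> communities -> classify.

A :class:`RunConfig` carries every tunable with defaults matching the study
settings (similarity floor 0.3, 20 ER replicates, 80% hold-out x 100
iterations, alpha 0.01, top-3 communities). :func:`run_pipeline` executes the
stages in order, writes one artifact per stage and a manifest with seeds,
parameters and stage checksums, and is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from csncrit import classify, communities, mcs, mol_io, sweep

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "csn_out"
    floor: float = 0.3
    grid_start: float = 0.3
    grid_stop: float = 1.0
    grid_step: float = 0.01
    er_replicates: int = 20
    holdout: float = 0.8
    cv_iterations: int = 100
    alpha: float = 0.01
    top_k: int = 3
    min_variability: float = 0.10
    criterion: str = "betweenness_peak"
    seed: int = 0

    def validate(self) -> None:
        if self.grid_start < self.floor:
            raise ValueError(
                f"grid start {self.grid_start} below similarity floor {self.floor}"
            )
        if not 0.0 < self.holdout < 1.0:
            raise ValueError("holdout must be in (0, 1)")
        if self.er_replicates < 1 or self.cv_iterations < 1:
            raise ValueError("replicate/iteration counts must be >= 1")

    def grid(self) -> np.ndarray:
        return sweep.default_grid(self.grid_start, self.grid_stop, self.grid_step)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, molset: mol_io.MoleculeSet | None = None) -> dict:
    """Run every stage and return the manifest (also written to disk).

    ``molset`` may be passed directly (e.g. a synthetic set); otherwise the
    configured input tables are read and merged.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {p.name: _checksum(p) for p in paths}

    # 1. curation
    if molset is None:
        if not config.inputs:
            raise ValueError("no input tables configured and no molecule set passed")
        sets = [mol_io.read_smiles_table(p) for p in config.inputs]
    else:
        sets = [molset]
    curated, conflicts = mol_io.merge_and_deduplicate(sets)
    curated_path = out / "curated.csv"
    conflict_path = out / "conflicts.json"
    curated.to_csv(curated_path)
    conflicts.to_json(conflict_path)
    record("curate", curated_path, conflict_path)
    logger.info("curated %d molecules (%d conflicts discarded)", curated.n,
                conflicts.n_discarded)

    # 2. pairwise similarity (checkpointed: reused when inputs are unchanged)
    edges_path = out / "similarities.csv"
    meta_path = out / "similarities.meta.json"
    input_checksum = _checksum(curated_path)
    reuse = False
    if edges_path.exists() and meta_path.exists():
        try:
            meta = json.loads(meta_path.read_text())
            reuse = meta.get("input_checksum") == input_checksum
        except (json.JSONDecodeError, OSError):
            reuse = False
    if reuse:
        store = mcs.SimilarityStore.from_csv(edges_path, meta_path)
        logger.info("reusing checkpointed similarity store (%d pairs)", len(store.entries))
    else:
        store = mcs.pairwise_similarity(curated, floor=config.floor)
        store.to_csv(edges_path, meta_path)
        meta = json.loads(meta_path.read_text())
        meta["input_checksum"] = input_checksum
        meta_path.write_text(json.dumps(meta, indent=2))
        if store.timeouts:
            logger.warning("%d molecule pairs hit the MCS expansion cap", len(store.timeouts))
    record("similarity", edges_path, meta_path)

    # 3. threshold sweep vs ER ensembles
    sweep_result = sweep.threshold_sweep(
        store, grid=config.grid(), n_er=config.er_replicates, seed=config.seed
    )
    sweep_path = out / "sweep.csv"
    sweep_result.to_csv(sweep_path)
    record("sweep", sweep_path)

    # 4. critical point
    critical = sweep.detect_critical_point(sweep_result, criterion=config.criterion)
    crit_path = out / "critical_point.json"
    critical.to_json(crit_path)
    record("critical_point", crit_path)
    logger.info("critical point: t=%.3f p=%.4g (%s)", critical.t_crit,
                critical.p_crit, critical.criterion)

    # 5. communities at criticality
    from csncrit.network import build_network

    net = build_network(store, critical.t_crit)
    partition = communities.louvain_partition(net, seed=config.seed)
    part_csv = out / "communities.csv"
    part_json = out / "communities.json"
    partition.to_files(part_csv, part_json)
    record("communities", part_csv, part_json)

    # 6. descriptor screen on the top communities
    screen_path = out / "descriptor_screen.csv"
    try:
        table = communities.compute_descriptors(curated.smiles())
        table = communities.descriptor_filter(table, config.min_variability)
        screen = communities.community_descriptor_screen(
            table, partition, top_k=config.top_k, alpha=config.alpha
        )
        screen.to_csv(screen_path)
        record("screen", screen_path)
        manifest["n_significant_descriptors"] = screen.n_significant
    except ValueError as exc:
        logger.warning("descriptor screen skipped: %s", exc)
        manifest["stages"]["screen"] = {"skipped": str(exc)}

    # 7. classification at the critical threshold
    report = classify.holdout_cv(
        store,
        curated.labels(),
        t=critical.t_crit,
        holdout=config.holdout,
        iters=config.cv_iterations,
        seed=config.seed,
    )
    cls_path = out / "classification.json"
    report.to_json(cls_path)
    record("classify", cls_path)

    manifest["critical_point"] = {
        "t_crit": critical.t_crit, "p_crit": critical.p_crit,
        "criterion": critical.criterion,
    }
    manifest["n_molecules"] = curated.n
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
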