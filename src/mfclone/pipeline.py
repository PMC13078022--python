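"""End-to-end pipeline: simulate/ingest -> score pairs -> classify ->
build units -> similarity -> group comparisons.

One :class:`PipelineConfig` (YAML/JSON-loadable) drives every stage; all
randomness flows from the single master seed through named substreams, so
a rerun with identical config and seed reproduces identical outputs.  A
manifest (config hash, seeds, per-stage row counts) is written next to
the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clonality, lineage, similarity
from .io import Cohort, load_cohort
from .simulate import GroundTruth, SimulationConfig, simulate_cohort, write_fixture
from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run.

    Exactly one of ``inputs`` (paths to cohort tables) or ``simulation``
    must be provided.
    """

    out_dir: str = "results/run"
    master_seed: int = 0
    inputs: Optional[Dict[str, str]] = None      # sample_sheet, mutations, ...
    simulation: Optional[SimulationConfig] = None
    n_perm: int = 999
    alpha_clonal: float = 0.05
    f_min: Optional[float] = None
    n_inter: int = 50
    correlation_method: str = "spearman"
    callable_mb: float = 35.0
    driver_genes: Optional[List[str]] = None
    gene_sets: Dict[str, List[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValidationError(
                "exactly one of 'inputs' and 'simulation' must be configured"
            )
        if self.inputs is not None:
            missing = [
                f"{k}: {v}" for k, v in self.inputs.items() if not Path(v).exists()
            ]
            if missing:
                raise ValidationError(f"input file(s) not found: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim is not None:
            if "nodules_per_patient" in sim:
                sim["nodules_per_patient"] = tuple(sim["nodules_per_patient"])
            if "biopsies_per_nodule" in sim:
                sim["biopsies_per_nodule"] = tuple(sim["biopsies_per_nodule"])
            if "driver_genes" in sim:
                sim["driver_genes"] = tuple(sim["driver_genes"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _substream(master_seed: int, name: str) -> int:
    digest = hashlib.blake2b(f"{master_seed}|{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    substream_seeds: Dict[str, int]
    row_counts: Dict[str, int]
    wall_time_s: float
    outputs: Dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; write TSV outputs and a manifest under out_dir."""
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        "simulation": _substream(config.master_seed, "simulation"),
        "clonality": _substream(config.master_seed, "clonality"),
        "inter_patient_sampling": _substream(config.master_seed, "inter_patient"),
    }
    outputs: Dict[str, str] = {}
    row_counts: Dict[str, int] = {}
    stage = "load"
    try:
        truth: Optional[GroundTruth] = None
        if config.simulation is not None:
            stage = "simulate"
            sim_cfg = config.simulation
            sim_cfg.seed = seeds["simulation"]
            cohort, truth = simulate_cohort(sim_cfg)
            fixture_paths = write_fixture(cohort, truth, out / "cohort")
            outputs.update({k: str(v) for k, v in fixture_paths.items()})
            logger.info("simulate: %d samples", len(cohort.samples))
        else:
            cohort = load_cohort(
                sample_sheet=config.inputs["sample_sheet"],
                mutations=config.inputs.get("mutations"),
                copy_number=config.inputs.get("copy_number"),
                expression=config.inputs.get("expression"),
                signatures=config.inputs.get("signatures"),
                f_min=config.f_min,
                driver_genes=config.driver_genes or (),
            )
        if config.driver_genes:
            cohort.driver_genes = tuple(config.driver_genes)
        row_counts["samples"] = len(cohort.samples)

        stage = "score_pairs"
        results = clonality.score_all_pairs(
            cohort,
            n_perm=config.n_perm,
            alpha_clonal=config.alpha_clonal,
            master_seed=seeds["clonality"],
            f_min=config.f_min,
        )
        pairs_df = clonality.results_to_frame(results, cohort)
        pairs_path = out / "pairs.tsv"
        pairs_df.to_csv(pairs_path, sep="\t", index=False)
        outputs["pairs"] = str(pairs_path)
        row_counts["pairs"] = len(pairs_df)
        logger.info(
            "score_pairs: %d pairs, %d clonal",
            len(results), sum(r.call == "clonal" for r in results),
        )

        stage = "classify"
        classifications, units, relations = lineage.classify_cohort(cohort, results)
        patients_df = pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "label": c.label,
                    "n_clonal_pairs": c.n_clonal_pairs,
                    "n_nonclonal_pairs": c.n_nonclonal_pairs,
                }
                for c in classifications
            ]
        )
        patients_path = out / "patients.tsv"
        patients_df.to_csv(patients_path, sep="\t", index=False)
        units_df = pd.DataFrame(
            [
                {
                    "unit_id": u.unit_id,
                    "patient_id": u.patient_id,
                    "kind": u.kind,
                    "nodules": ",".join(sorted(u.member_nodules)),
                    "biopsies": ",".join(u.member_biopsies),
                    "representatives": ",".join(u.representative_biopsies),
                }
                for u in units
            ]
        )
        units_path = out / "units.tsv"
        units_df.to_csv(units_path, sep="\t", index=False)
        outputs["patients"] = str(patients_path)
        outputs["units"] = str(units_path)
        row_counts["patients"] = len(patients_df)
        row_counts["units"] = len(units_df)

        stage = "similarity"
        records = similarity.enumerate_pair_classes(
            cohort, results, n_inter=config.n_inter,
            seed=seeds["inter_patient_sampling"],
        )
        similarity.compute_pair_metrics(
            records, cohort, method=config.correlation_method
        )
        sim_df = similarity.records_to_frame(records)
        sim_path = out / "pair_classes.tsv"
        sim_df.to_csv(sim_path, sep="\t", index=False)
        outputs["pair_classes"] = str(sim_path)
        row_counts["pair_classes"] = len(sim_df)

        stage = "compare"
        comparisons = unit_comparisons(cohort, units, config)
        cmp_path = out / "comparisons.tsv"
        comparisons.to_csv(cmp_path, sep="\t", index=False)
        outputs["comparisons"] = str(cmp_path)
        row_counts["comparisons"] = len(comparisons)
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %r", stage)
        raise

    manifest = RunManifest(
        config_hash=config.config_hash(),
        master_seed=config.master_seed,
        substream_seeds=seeds,
        row_counts=row_counts,
        wall_time_s=round(time.time() - t0, 3),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def unit_comparisons(
    cohort: Cohort, units: Sequence[lineage.TumorUnit], config: PipelineConfig
) -> pd.DataFrame:
    """TMP-vs-TNEM comparisons of FGA, TMB and driver alteration counts.

    FGA and driver counts use the unit-level aggregates (max-deviation CN,
    union of mutations); TMB uses the representative (first) biopsies.
    """
    from .stats import compare_numeric_groups

    rows = []
    groups_fga: Dict[str, List[float]] = {"TMP": [], "TNEM": []}
    groups_tmb: Dict[str, List[float]] = {"TMP": [], "TNEM": []}
    groups_drv: Dict[str, List[float]] = {"TMP": [], "TNEM": []}
    for u in units:
        if all(b in cohort.copy_number for b in u.member_biopsies) and u.member_biopsies:
            agg_cn = lineage.aggregate_copy_number(u, cohort.copy_number)
            groups_fga[u.kind].append(similarity.fraction_genome_altered(agg_cn))
        if all(b in cohort.mutations for b in u.member_biopsies) and u.member_biopsies:
            agg_mut = lineage.aggregate_mutations(u, cohort.mutations)
            if cohort.driver_genes:
                groups_drv[u.kind].append(
                    similarity.driver_alteration_count(agg_mut, cohort.driver_genes)
                )
            reps = [b for b in u.representative_biopsies if b in cohort.mutations]
            if reps:
                tmb = float(
                    np.mean(
                        [
                            similarity.tumor_mutational_burden(
                                cohort.mutations[b], config.callable_mb
                            )
                            for b in reps
                        ]
                    )
                )
                groups_tmb[u.kind].append(tmb)
    for feature, groups in (
        ("fraction_genome_altered", groups_fga),
        ("tumor_mutational_burden", groups_tmb),
        ("driver_alteration_count", groups_drv),
    ):
        if all(len(v) for v in groups.values()):
            cmp = compare_numeric_groups(groups, feature=feature)
            rows.append(
                {
                    "feature": feature,
                    "test": cmp.test,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "median_TMP": cmp.group_summaries["TMP"]["median"],
                    "median_TNEM": cmp.group_summaries["TNEM"]["median"],
                    "n_TMP": cmp.group_summaries["TMP"]["n"],
                    "n_TNEM": cmp.group_summaries["TNEM"]["n"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "test", "statistic", "p_value",
            "median_TMP", "median_TNEM", "n_TMP", "n_TNEM",
        ],
    )
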