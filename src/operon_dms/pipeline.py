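"""Seeded, logged orchestration of the full analysis: simulate -> process ->
score -> features -> sd-scan -> associate.

Each stage reads only the previous stage's written outputs, so re-running a
single stage from cached inputs is reproducible. A JSON manifest records the
package version, parameters, per-stage record counts and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CountTable, OperonSpec, Variant
from . import synthetic_data as sd
from . import read_processing as rp
from . import enrichment
from . import codon_features as cf
from . import sd_hybridization as sdh
from . import association_stats as assoc

log = logging.getLogger("operon_dms")

STAGES = ("simulate", "process", "score", "features", "sd_scan", "associate")

# fixed per-stage seed offsets fanned out from the global seed
_STAGE_SEED_OFFSET = {"simulate": 11, "process": 23, "score": 37, "features": 41,
                      "sd_scan": 53, "associate": 67}


@dataclass
class PipelineConfig:
    outdir: str = "operon_dms_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulation
    n_codons: int = 72
    mutagenized_start: int = 2
    rbs_region: tuple[int, int] | None = (70, 71)
    wt_fraction: float = 0.10
    rcu_coefficient: float = 1.0
    noise_sd: float = 0.3
    depth_per_replicate: int = 100_000
    n_replicates: int = 3
    q_score: int = 35
    sequencing_error_rate: float = 0.0
    # processing
    q_cutoff: float = 20
    min_length: int = 75
    gap_open: float = rp.ALIGN_GAP_OPEN
    gap_extend: float = rp.ALIGN_GAP_EXTEND
    # scoring
    min_unselected_reads: int = 20
    generations: int = enrichment.DEFAULT_GENERATIONS
    # tables (None -> packaged defaults)
    usage_table: str | None = None
    trna_table: str | None = None
    stall_table: str | None = None
    # association
    activity_threshold: float = assoc.ACTIVITY_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.rbs_region is not None:
            cfg.rbs_region = tuple(cfg.rbs_region)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# operon-dms {__version__}\n")
        for k, v in params.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "checksums": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            counts = _STAGE_RUNNERS[stage](config, out, state)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = counts
    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.fasta")):
        manifest["checksums"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed * 101 + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> dict:
    seed = _stage_seed(config, "simulate")
    gene = sd.random_gene(config.n_codons, seed=seed)
    rbs = config.rbs_region
    if rbs is not None and rbs[1] > config.n_codons:
        # mirror the canonical 70-71-of-72 placement for shorter toy genes
        rbs = (config.n_codons - 2, config.n_codons - 1)
    spec = OperonSpec(
        gene_id="toy_gene",
        coding_sequence=gene,
        mutagenized_positions=list(range(config.mutagenized_start, config.n_codons + 1)),
        rbs_region=rbs,
    )
    with open(out / "reference.fasta", "w") as fh:
        fh.write(f">{spec.gene_id}\n{gene}\n")
    variants = sd.enumerate_nnk_variants(spec)
    usage = cf.UsageTable(config.usage_table) if config.usage_table else cf.UsageTable.default()
    rcu_map = {
        v.variant_id: cf.rcu(v.wt_codon, v.mut_codon, usage)
        for v in variants
        if v.kind not in ("nonsense",)
    }
    model = sd.EffectModel(
        rcu_coefficient=config.rcu_coefficient, noise_sd=config.noise_sd, seed=seed
    )
    library = sd.assign_true_effects(
        variants, model, rcu_map, wt_fraction=config.wt_fraction, spec=spec
    )
    sim_cfg = sd.SimConfig(
        depth_per_replicate=config.depth_per_replicate,
        n_replicates=config.n_replicates,
        q_score=config.q_score,
        sequencing_error_rate=config.sequencing_error_rate,
        seed=seed,
    )
    table = sd.simulate_counts(library, sim_cfg)
    table.to_tsv(out / "simulated_counts.tsv")
    library.truth_json(out / "true_survivals.json")
    fastqs = sd.emit_fastq(library, table, sim_cfg, str(out / "reads"))
    state.update(spec=spec, sim_config=sim_cfg, fastqs=fastqs, library=library)
    return {"variants": len(variants), "replicates": config.n_replicates,
            "depth": config.depth_per_replicate}


def _stage_process(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "spec" not in state:
        raise StageError("process", ValueError(
            "process requires the simulate stage (or externally provided reads)"))
    spec: OperonSpec = state["spec"]
    table, summary = rp.process_replicates(
        state["fastqs"],
        spec.coding_sequence,
        state["sim_config"].mid_tags,
        q_cutoff=config.q_cutoff,
        min_length=config.min_length,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    table.to_tsv(out / "counts.tsv")
    _write_tsv(summary, out / "rejection_summary.tsv",
               {"q_cutoff": config.q_cutoff, "min_length": config.min_length}, index=False)
    state["counts"] = table
    return {"counted": int(table.totals.sum()),
            "rejected": int(summary.loc[summary.reason.str.startswith("reject"), "count"].sum())}


def _stage_score(config: PipelineConfig, out: Path, state: dict) -> dict:
    table = state.get("counts")
    if table is None:
        path = out / "counts.tsv"
        if not path.exists():
            path = out / "simulated_counts.tsv"
        if not path.exists():
            raise StageError("score", FileNotFoundError("no count table found; run process or simulate"))
        table = CountTable.from_tsv(path)
    records = enrichment.score_table(
        table, min_unselected_reads=config.min_unselected_reads,
        n_generations=config.generations,
    )
    _write_tsv(records, out / "scores.tsv",
               {"min_unselected_reads": config.min_unselected_reads,
                "generations": config.generations})
    summary = enrichment.position_summary(records)
    _write_tsv(summary, out / "position_summary.tsv", {})
    state["records"] = records
    return {"scored": int(records["es_mean"].notna().sum()), "total": len(records)}


def _stage_features(config: PipelineConfig, out: Path, state: dict) -> dict:
    records = state.get("records")
    if records is None:
        raise StageError("features", ValueError("features requires the score stage"))
    spec: OperonSpec = state["spec"]
    usage = cf.UsageTable(config.usage_table) if config.usage_table else cf.UsageTable.default()
    trna = cf.SimpleCodonTable(config.trna_table) if config.trna_table else cf.SimpleCodonTable.default_trna()
    stall = cf.SimpleCodonTable(config.stall_table) if config.stall_table else cf.SimpleCodonTable.default_stalling()
    feats = cf.feature_table(records, spec.coding_sequence, usage, trna, stall)
    _write_tsv(feats, out / "features.tsv", {"usage": usage.source})
    state["features"] = feats
    return {"variants": len(feats)}


def _stage_sd_scan(config: PipelineConfig, out: Path, state: dict) -> dict:
    spec: OperonSpec = state.get("spec")
    records = state.get("records")
    if spec is None or records is None:
        raise StageError("sd_scan", ValueError("sd_scan requires simulate and score stages"))
    rows = []
    if spec.rbs_region is not None:
        lo, hi = spec.rbs_region
        wt_dg = sdh.rbs_strength(spec.coding_sequence, spec.rbs_region)
        for vid, rec in records.iterrows():
            if lo <= rec["position"] <= hi and rec["kind"] != "wt":
                v = Variant(int(rec["position"]), rec["wt_codon"], rec["mut_codon"])
                dg = sdh.rbs_strength(spec.coding_sequence, spec.rbs_region, v)
                rows.append({"variant_id": vid, "dg_bind": round(dg, 1),
                             "ddg_vs_wt": round(dg - wt_dg, 1)})
    df = pd.DataFrame(rows).set_index("variant_id") if rows else pd.DataFrame(
        columns=["dg_bind", "ddg_vs_wt"])
    _write_tsv(df, out / "rbs_strength.tsv", {"rbs_region": spec.rbs_region})
    state["rbs"] = df
    return {"rbs_variants": len(df)}


def _stage_associate(config: PipelineConfig, out: Path, state: dict) -> dict:
    records = state.get("records")
    feats = state.get("features")
    if records is None or feats is None:
        raise StageError("associate", ValueError(
            "associate requires the score and features stages to have run"))
    report = assoc.feature_association_report(records, feats, threshold=config.activity_threshold)
    boxes = assoc.box_stats_table(records, feats, threshold=config.activity_threshold)
    _write_tsv(report, out / "association_report.tsv",
               {"threshold": config.activity_threshold})
    _write_tsv(boxes, out / "box_stats.tsv", {}, index=False)
    return {"features_tested": int((~report["missing"]).sum()) if "missing" in report else 0}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "score": _stage_score,
    "features": _stage_features,
    "sd_scan": _stage_sd_scan,
    "associate": _stage_associate,
}
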