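"""Config-driven orchestration of the full analysis.

Stages run in the order QC -> per-sample consensus-NMF programs ->
robust-program selection and meta-program clustering -> signature
scoring and the MHC-II gate -> R_o/e enrichment -> spatial
colocalization.  Every stage is individually skippable; all stage
parameters default to the study's printed values (K 4..12, 200 NMF
replicates, 30-gene signatures, 200/8000/10% QC bounds, 1000
permutations at an 80% subsample).

A run is driven by one flat key:value YAML config and a single seed;
every random decision derives from that seed through a spawned seed
sequence, so identical config + seed reproduces every numeric output
byte for byte.  A run report (parameters, shapes, seeds, wall times,
warnings) is serialised next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, enrichment, programs, scoring, spatial, synthdata
from .core_io import ConfigError


@dataclass
class RunConfig:
    """Flat, typed configuration of one pipeline run."""

    outdir: str = "metaniche_run"
    seed: int = 0

    # input: either an MTX directory or the synthetic cohort generator
    counts_dir: str | None = None
    synthetic: bool = True
    n_samples: int = 3
    cells_per_sample: int = 200
    n_genes: int = 500
    n_celltypes: int = 3
    n_planted_programs: int = 3
    planted_program_size: int = 50
    planted_log_fold: float = 2.0
    planted_fraction: float = 0.3
    mhc2_basal_fraction: float = 0.2
    nb_dispersion: float = 0.4

    # stage toggles
    run_qc: bool = True
    run_programs: bool = True
    run_scoring: bool = True
    run_roe: bool = True
    run_spatial: bool = True

    # QC
    min_genes: int = 200
    max_genes: int = 8000
    max_mito: float = 0.10

    # programs / meta-programs
    k_min: int = 4
    k_max: int = 12
    n_replicates: int = 200
    top_genes_per_program: int = 50
    n_hvg: int = 2000
    intra_overlap_min: int = 35
    inter_overlap_min: int = 10
    min_join_overlap: int = 10
    signature_size: int = 30

    # scoring
    n_bins: int = 24
    n_ctrl: int = 100
    top_fraction: float = 0.05
    mhc2_genes: tuple[str, str, str, str] = scoring.MHC2_DEFAULT_GENES

    # spatial
    spot_file: str | None = None
    synthetic_spatial: bool = True
    spatial_grid: tuple[int, int] = (20, 20)
    spatial_celltypes: int = 4
    n_perm: int = 1000
    subsample_fraction: float = 0.8
    n_factors: int = 3

    def validate(self) -> list[str]:
        errs = []
        if self.k_min < 2:
            errs.append("k_min must be >= 2")
        if self.k_min > self.k_max:
            errs.append(f"k_min ({self.k_min}) must not exceed k_max ({self.k_max})")
        for name in ("max_mito", "top_fraction", "subsample_fraction",
                     "planted_fraction", "mhc2_basal_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                errs.append(f"{name} must lie in [0, 1], got {v}")
        if self.subsample_fraction == 0:
            errs.append("subsample_fraction must be positive")
        if self.n_replicates < 2:
            errs.append("n_replicates must be >= 2")
        if self.min_genes < 0 or self.max_genes < self.min_genes:
            errs.append("QC gene bounds must satisfy 0 <= min_genes <= max_genes")
        if len(self.mhc2_genes) != 4:
            errs.append("mhc2_genes must list exactly four genes")
        return errs


def validate_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config, applying defaults; accumulate all errors."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errs = [f"unknown config key {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.mhc2_genes, list):
        cfg.mhc2_genes = tuple(cfg.mhc2_genes)
    if isinstance(cfg.spatial_grid, list):
        cfg.spatial_grid = tuple(cfg.spatial_grid)
    errs.extend(cfg.validate())
    if errs:
        raise ConfigError("; ".join(errs))
    return cfg


def _planted_cohort_config(cfg: RunConfig, seed: int) -> synthdata.CohortConfig:
    """Cohort config with disjoint planted activity programs mid-range."""
    reserved = 10 + 20 + 4  # MT / RP block + gate genes
    planted = []
    start = reserved + 6
    for j in range(cfg.n_planted_programs):
        genes = tuple(range(start, start + cfg.planted_program_size))
        if genes and genes[-1] >= cfg.n_genes:
            raise ConfigError("n_genes too small for the planted programs")
        planted.append(
            synthdata.PlantedProgram(genes, cfg.planted_fraction, cfg.planted_log_fold)
        )
        start += cfg.planted_program_size
    groups = {}
    for i in range(cfg.n_samples):
        sid = f"S{i + 1:02d}"
        groups[sid] = "MI-basal" if i % 2 == 0 else "MI-luminal"
    return synthdata.CohortConfig(
        n_samples=cfg.n_samples,
        cells_per_sample=cfg.cells_per_sample,
        n_genes=cfg.n_genes,
        n_celltypes=cfg.n_celltypes,
        planted_programs=planted,
        group_labels=groups,
        nb_dispersion=cfg.nb_dispersion,
        mhc2_positive_fraction_by_group={"MI-basal": cfg.mhc2_basal_fraction},
        seed=seed,
    )


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict."""
    errs = cfg.validate()
    if errs:
        raise ConfigError("; ".join(errs))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(dataclasses.asdict(cfg)), "stages": {}}
    manifest: dict[str, str] = {}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seed = {name: int(s) for name, s in zip(
        ("synth", "programs", "scoring", "spatial"),
        ss.generate_state(4) % (2**31),
    )}
    caught: list[str] = []

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return done

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ------------------------------------------------ input
        done = _stage("input")
        if cfg.counts_dir is not None:
            d = Path(cfg.counts_dir)
            matrix = core_io.read_mtx(d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv")
            truth = None
        elif cfg.synthetic:
            cohort_cfg = _planted_cohort_config(cfg, stage_seed["synth"])
            matrix, truth = synthdata.generate_cohort(cohort_cfg)
            truth.to_json(outdir / "ground_truth.json")
            manifest["ground_truth"] = "ground_truth.json"
        else:
            raise ConfigError("stage input: neither counts_dir nor synthetic input configured")
        done(n_genes=matrix.n_genes, n_cells=matrix.n_cells)

        # ------------------------------------------------ QC
        if cfg.run_qc:
            done = _stage("qc")
            matrix, qcrep = core_io.qc_filter(
                matrix, cfg.min_genes, cfg.max_genes, cfg.max_mito
            )
            qcrep.to_json(outdir / "qc_report.json")
            manifest["qc_report"] = "qc_report.json"
            done(n_pass=int(qcrep.passed.sum()), n_total=len(qcrep.cell_ids))

        # ------------------------------------------------ programs + MPs
        mps: list[programs.MetaProgram] = []
        if cfg.run_programs:
            done = _stage("programs")
            stripped = core_io.strip_mito_ribo(matrix)
            pcfg_seed = np.random.SeedSequence(stage_seed["programs"])
            sample_ids = list(pd.unique(stripped.cell_meta["sample"]))
            sample_seeds = pcfg_seed.generate_state(len(sample_ids)) % (2**31)
            all_programs: list[programs.GeneProgram] = []
            for sid, sseed in zip(sample_ids, sample_seeds):
                sub = stripped.subset_cells(
                    (stripped.cell_meta["sample"] == sid).to_numpy()
                )
                pcfg = programs.ProgramSetConfig(
                    k_min=cfg.k_min,
                    k_max=cfg.k_max,
                    n_replicates=cfg.n_replicates,
                    top_genes_per_program=cfg.top_genes_per_program,
                    n_hvg=cfg.n_hvg,
                    seed=int(sseed),
                )
                progs, _ = programs.programs_for_sample(sub, pcfg)
                all_programs.extend(progs)
            robust = programs.select_robust(
                all_programs, cfg.intra_overlap_min, cfg.inter_overlap_min
            )
            if robust:
                mps = programs.cluster_metaprograms(
                    robust, cfg.min_join_overlap, cfg.signature_size
                )
            _write_mps(outdir / "metaprograms.json", all_programs, robust, mps)
            manifest["metaprograms"] = "metaprograms.json"
            done(
                n_programs=len(all_programs),
                n_robust=len(robust),
                n_metaprograms=len(mps),
            )

        # ------------------------------------------------ scoring + gate
        if cfg.run_scoring:
            done = _stage("scoring")
            gate = scoring.mhc2_gate(matrix, cfg.mhc2_genes)
            gate_df = pd.DataFrame(
                {
                    "cell_id": matrix.cell_ids,
                    "sample": matrix.cell_meta["sample"].to_numpy(),
                    "mhc2_positive": gate.positive.to_numpy(),
                }
            )
            gate_df.to_csv(outdir / "mhc2_gate.tsv", sep="\t", index=False)
            gate.fraction_by_sample.rename("fraction").to_csv(
                outdir / "mhc2_fractions.tsv", sep="\t"
            )
            manifest["mhc2_gate"] = "mhc2_gate.tsv"
            score_info = {}
            if mps:
                sc = scoring.module_score(
                    matrix,
                    mps[0].signature,
                    name=mps[0].mp_id,
                    n_bins=cfg.n_bins,
                    n_ctrl=cfg.n_ctrl,
                    seed=stage_seed["scoring"],
                )
                sc.values.rename(sc.name).to_csv(outdir / "mp_scores.tsv", sep="\t")
                manifest["mp_scores"] = "mp_scores.tsv"
                score_info["scored_mp"] = mps[0].mp_id
            done(n_positive=int(gate.positive.sum()), **score_info)

        # ------------------------------------------------ R_o/e
        if cfg.run_roe:
            done = _stage("roe")
            table = enrichment.roe_from_cells(matrix.cell_meta)
            table.ratio.to_csv(outdir / "roe.tsv", sep="\t")
            manifest["roe"] = "roe.tsv"
            done(n_clusters=len(table.ratio), n_groups=table.ratio.shape[1])

        # ------------------------------------------------ spatial
        if cfg.run_spatial:
            done = _stage("spatial")
            if cfg.spot_file is not None:
                spots = spatial.SpotAbundance.from_tsv(cfg.spot_file)
            elif cfg.synthetic_spatial:
                rows, cols_ = cfg.spatial_grid
                sp_cfg = synthdata.SpatialConfig(
                    grid_shape=cfg.spatial_grid,
                    n_celltypes=cfg.spatial_celltypes,
                    niches=[
                        synthdata.SpatialNiche(
                            (rows * 0.3, cols_ * 0.3), max(2.0, rows * 0.15), (0, 1)
                        ),
                        synthdata.SpatialNiche(
                            (rows * 0.7, cols_ * 0.7), max(2.0, rows * 0.15), (2,)
                        ),
                    ],
                    seed=stage_seed["spatial"],
                )
                spots, sp_truth = synthdata.generate_spatial(sp_cfg)
            else:
                raise ConfigError(
                    "stage spatial: enabled but no spot_file given and "
                    "synthetic_spatial is off"
                )
            skl, pmat, results = spatial.coloc_all_pairs(
                spots,
                n_perm=cfg.n_perm,
                frac=cfg.subsample_fraction,
                seed=stage_seed["spatial"],
            )
            skl.to_csv(outdir / "coloc_skl.tsv", sep="\t")
            pmat.to_csv(outdir / "coloc_p.tsv", sep="\t")
            payload = [
                {
                    "type1": r.type1,
                    "type2": r.type2,
                    "observed_skl": r.observed,
                    "p_value": r.p_value,
                    "n_perm": r.n_perm,
                    "subsample_fraction": r.subsample_fraction,
                }
                for r in results
            ]
            (outdir / "coloc.json").write_text(json.dumps(payload, indent=1))
            manifest["coloc"] = "coloc.json"
            loadings, weights = spatial.compartment_nmf(
                spots, cfg.n_factors, seed=stage_seed["spatial"]
            )
            weights.to_csv(outdir / "compartment_weights.tsv", sep="\t")
            manifest["compartment_weights"] = "compartment_weights.tsv"
            done(n_spots=spots.n_spots, n_pairs=len(results))

        caught = [str(w.message) for w in wrec]

    report["seeds"] = stage_seed
    report["warnings"] = caught
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _write_mps(path: Path, all_programs, robust, mps) -> None:
    robust_keys = {p.key for p in robust}
    payload = {
        "n_programs": len(all_programs),
        "n_robust": len(robust),
        "programs": [
            {
                "sample": p.sample_id,
                "k": p.k,
                "index": p.program_index,
                "robust": p.key in robust_keys,
                "top_genes": p.top_genes,
            }
            for p in all_programs
        ],
        "metaprograms": [
            {
                "mp_id": mp.mp_id,
                "signature": mp.signature,
                "member_samples": sorted(mp.member_samples),
                "members": [list(map(str, p.key)) for p in mp.member_programs],
            }
            for mp in mps
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
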