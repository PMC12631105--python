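"""Synthetic multi-sample single-cell cohorts and spatial grids with
planted ground truth.

The cohort generator emulates the data structure of a multi-sample
urothelial-carcinoma study: per-sample negative-binomial counts carrying

* cell-type identity programs (disjoint marker-gene blocks upregulated
  in each cell type),
* planted activity programs (a gene set upregulated by a log2 fold
  change in a random fraction of cells, recorded in the ground truth),
* an MHC-II-positive cell population restricted per pathology group
  (cells guaranteed strictly positive counts on the four gate genes
  HLA-DRA / HLA-DRB1 / HLA-DPA1 / HLA-DPB1).

Counts are gamma-Poisson (negative binomial) with a single shared
dispersion and per-cell log-normal library-size factors, so QC and
normalisation downstream are non-trivial.  Mitochondrial and ribosomal
genes carry the conventional MT- / RPL / RPS name prefixes so the QC
stage recognises them exactly as it would in real data.

The spatial generator lays Gaussian "niche" bumps shared by member cell
types over a rectangular spot grid on top of a uniform background plus
truncated Gaussian noise, yielding spot x cell-type abundance tables
with known colocalization structure.

One global seed spawns per-sample seed sequences, so individual samples
are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ConfigError, CountMatrix
from .spatial import SpotAbundance

GROUPS = ("Normal", "NMI", "MI-luminal", "MI-basal")
MHC2_GENE_NAMES = ("HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1")


@dataclass
class PlantedProgram:
    """A gene set activated (x 2**log_fold) in a fraction of cells."""

    genes: tuple[int, ...]
    fraction: float
    log_fold: float

    def __post_init__(self) -> None:
        self.genes = tuple(int(g) for g in self.genes)
        if not 0 <= self.fraction <= 1:
            raise ConfigError("program fraction must be in [0, 1]")


@dataclass
class CohortConfig:
    """Parameters of a synthetic multi-sample cohort.

    Defaults give 3 samples x 200 cells x 500 genes with 3 cell types —
    small enough to run the whole pipeline in seconds while leaving QC,
    HVG selection and NMF with realistic work to do.
    """

    n_samples: int = 3
    cells_per_sample: int = 200
    n_genes: int = 500
    n_celltypes: int = 3
    planted_programs: list[PlantedProgram] = field(default_factory=list)
    group_labels: dict[str, str] | None = None
    tissue_labels: dict[str, str] | None = None
    mito_gene_count: int = 10
    ribo_gene_count: int = 20
    nb_dispersion: float = 0.4
    mhc2_gene_indices: tuple[int, int, int, int] | None = None
    mhc2_positive_fraction_by_group: dict[str, float] = field(default_factory=dict)
    markers_per_celltype: int = 25
    celltype_marker_log_fold: float = 1.5
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.8
    libsize_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.cells_per_sample < 1:
            raise ConfigError("need at least one sample and one cell per sample")
        if self.n_genes < 1:
            raise ConfigError("need at least one gene")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        self.planted_programs = [
            p if isinstance(p, PlantedProgram) else PlantedProgram(*p)
            for p in self.planted_programs
        ]
        union = set().union(*(p.genes for p in self.planted_programs), set())
        if union and (min(union) < 0 or max(union) >= self.n_genes):
            raise ConfigError("planted gene sets must lie within the gene range")
        if self.group_labels is None:
            self.group_labels = {
                self.sample_id(i): GROUPS[i % len(GROUPS)] for i in range(self.n_samples)
            }
        if self.tissue_labels is None:
            self.tissue_labels = {
                s: ("UTUC" if i % 2 else "UCB")
                for i, s in enumerate(self.group_labels)
            }
        bad = set(self.group_labels.values()) - set(GROUPS)
        if bad:
            raise ConfigError(f"unknown pathology groups {sorted(bad)}")
        if self.mhc2_gene_indices is None:
            start = self.mito_gene_count + self.ribo_gene_count
            self.mhc2_gene_indices = tuple(range(start, start + 4))
        self.mhc2_gene_indices = tuple(int(i) for i in self.mhc2_gene_indices)
        if len(set(self.mhc2_gene_indices)) != 4:
            raise ConfigError("mhc2_gene_indices must be 4 distinct gene indices")
        if max(self.mhc2_gene_indices) >= self.n_genes:
            raise ConfigError("mhc2_gene_indices out of gene range")
        for g, f in self.mhc2_positive_fraction_by_group.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if not 0 <= f <= 1:
                raise ConfigError("mhc2 positive fractions must lie in [0, 1]")

    def sample_id(self, i: int) -> str:
        return f"S{i + 1:02d}"

    def gene_names(self) -> list[str]:
        """Gene names with MT-/RPL/RPS prefixes and the four HLA gate genes."""
        names = []
        ribo_half = self.ribo_gene_count // 2
        for i in range(self.n_genes):
            if i < self.mito_gene_count:
                names.append(f"MT-G{i + 1}")
            elif i < self.mito_gene_count + ribo_half:
                names.append(f"RPL{i + 1}")
            elif i < self.mito_gene_count + self.ribo_gene_count:
                names.append(f"RPS{i + 1}")
            else:
                names.append(f"GENE{i + 1:05d}")
        for idx, hla in zip(self.mhc2_gene_indices, MHC2_GENE_NAMES):
            if idx < self.mito_gene_count + self.ribo_gene_count:
                raise ConfigError("mhc2 genes cannot sit inside the MT-/RP block")
            names[idx] = hla
        return names

    def celltype_marker_indices(self) -> list[np.ndarray]:
        """Disjoint marker blocks taken from the tail of the gene range."""
        blocks = []
        end = self.n_genes
        for t in range(self.n_celltypes):
            start = end - self.markers_per_celltype
            if start < self.mito_gene_count + self.ribo_gene_count:
                raise ConfigError("not enough genes for the cell-type marker blocks")
            blocks.append(np.arange(start, end))
            end = start
        return blocks


@dataclass
class SpatialNiche:
    """A Gaussian abundance bump shared by its member cell types."""

    center: tuple[float, float]
    radius: float
    members: tuple[int, ...]
    amplitude: float = 5.0


@dataclass
class SpatialConfig:
    grid_shape: tuple[int, int] = (20, 20)
    n_celltypes: int = 4
    niches: list[SpatialNiche] = field(default_factory=list)
    background_intensity: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_intensity < 0:
            raise ConfigError("background intensity must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        self.niches = [
            n if isinstance(n, SpatialNiche) else SpatialNiche(*n) for n in self.niches
        ]
        rows, cols = self.grid_shape
        for n in self.niches:
            r, c = n.center
            if not (0 <= r < rows and 0 <= c < cols):
                raise ConfigError(f"niche center {n.center} outside the grid")
            if any(m < 0 or m >= self.n_celltypes for m in n.members):
                raise ConfigError("niche member index outside cell-type range")


@dataclass
class GroundTruth:
    """Planted truth for one generated object (cohort or spatial grid)."""

    program_membership: pd.DataFrame | None = None  # cells x programs, bool
    celltype: pd.Series | None = None  # per cell
    mhc2_positive: pd.Series | None = None  # per cell
    niche_id: pd.Series | None = None  # per spot

    def to_json(self, path: str | Path) -> None:
        payload: dict = {}
        if self.program_membership is not None:
            payload["program_membership"] = {
                c: self.program_membership[c].astype(bool).tolist()
                for c in self.program_membership.columns
            }
            payload["cell_ids"] = self.program_membership.index.tolist()
        if self.celltype is not None:
            payload["celltype"] = self.celltype.tolist()
        if self.mhc2_positive is not None:
            payload["mhc2_positive"] = self.mhc2_positive.astype(bool).tolist()
        if self.niche_id is not None:
            payload["niche_id"] = self.niche_id.tolist()
            payload["spot_ids"] = self.niche_id.index.tolist()
        Path(path).write_text(json.dumps(payload))


def generate_cohort(config: CohortConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a multi-sample cohort of NB counts with planted structure."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *sample_ss = root.spawn(config.n_samples + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    G = config.n_genes
    baseline = cohort_rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, G)
    marker_blocks = config.celltype_marker_indices()
    marker_fold = 2.0 ** config.celltype_marker_log_fold

    gene_names = config.gene_names()
    samples = list(config.group_labels)
    blocks, metas, memberships, celltypes, mhc2_flags = [], [], [], [], []

    for sid, ss in zip(samples, sample_ss):
        rng = np.random.default_rng(ss)
        n = config.cells_per_sample
        group = config.group_labels[sid]
        tissue = config.tissue_labels[sid]

        # per-sample mild gene-level wobble so samples are not identical
        sample_factor = rng.lognormal(0.0, 0.1, G)
        mean = np.repeat((baseline * sample_factor)[:, None], n, axis=1)

        ct = rng.integers(0, config.n_celltypes, size=n)
        for t, block in enumerate(marker_blocks):
            cols = np.flatnonzero(ct == t)
            if cols.size:
                mean[np.ix_(block, cols)] *= marker_fold

        member = np.zeros((n, len(config.planted_programs)), dtype=bool)
        for j, prog in enumerate(config.planted_programs):
            chosen = rng.random(n) < prog.fraction
            member[:, j] = chosen
            cols = np.flatnonzero(chosen)
            if cols.size:
                mean[np.ix_(np.array(prog.genes), cols)] *= 2.0 ** prog.log_fold

        libsize = rng.lognormal(0.0, config.libsize_log_sd, n)
        mean *= libsize[None, :]

        # gamma-Poisson: Var = mu + alpha * mu^2
        alpha = config.nb_dispersion
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mean * alpha)
        counts = rng.poisson(lam).astype(np.int64)

        f = config.mhc2_positive_fraction_by_group.get(group, 0.0)
        pos = np.zeros(n, dtype=bool)
        n_pos = int(round(f * n))
        if n_pos:
            idx = rng.choice(n, size=n_pos, replace=False)
            pos[idx] = True
            gate = np.array(config.mhc2_gene_indices)
            counts[np.ix_(gate, idx)] = np.maximum(counts[np.ix_(gate, idx)], 1)

        cell_ids = [f"{sid}_C{i + 1:04d}" for i in range(n)]
        blocks.append(sp.csr_matrix(counts))
        metas.append(
            pd.DataFrame(
                {
                    "sample": sid,
                    "group": group,
                    "tissue": tissue,
                    "celltype": [f"CT{t + 1}" for t in ct],
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
        )
        memberships.append(
            pd.DataFrame(
                member,
                index=cell_ids,
                columns=[f"program{j + 1}" for j in range(member.shape[1])],
            )
        )
        celltypes.append(pd.Series([f"CT{t + 1}" for t in ct], index=cell_ids))
        mhc2_flags.append(pd.Series(pos, index=cell_ids))

    meta = pd.concat(metas)
    matrix = CountMatrix(
        counts=sp.hstack(blocks, format="csr"),
        gene_ids=gene_names,
        cell_ids=meta.index.tolist(),
        cell_meta=meta,
    )
    truth = GroundTruth(
        program_membership=pd.concat(memberships),
        celltype=pd.concat(celltypes),
        mhc2_positive=pd.concat(mhc2_flags),
    )
    return matrix, truth


def generate_spatial(config: SpatialConfig) -> tuple[SpotAbundance, GroundTruth]:
    """Lay niche bumps over a grid and return spot x cell-type abundances."""
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.ravel().astype(float)
    cc = cc.ravel().astype(float)
    n_spots = rows * cols
    spot_ids = [f"spot{r:03.0f}x{c:03.0f}" for r, c in zip(rr, cc)]

    ab = np.full((n_spots, config.n_celltypes), config.background_intensity)
    niche_id = np.full(n_spots, -1)
    for k, niche in enumerate(config.niches):
        r0, c0 = niche.center
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        bump = niche.amplitude * np.exp(-d2 / (2.0 * niche.radius**2))
        for t in niche.members:
            ab[:, t] += bump
        inside = d2 <= niche.radius**2
        niche_id[inside] = k
    if config.noise_sd > 0:
        ab += rng.normal(0.0, config.noise_sd, ab.shape)
    ab = np.clip(ab, 0.0, None)

    types = [f"type{t + 1}" for t in range(config.n_celltypes)]
    abundance = SpotAbundance(
        abundances=pd.DataFrame(ab, index=pd.Index(spot_ids, name="spot_id"), columns=types),
        coordinates=pd.DataFrame(
            {"row": rr.astype(int), "col": cc.astype(int)},
            index=pd.Index(spot_ids, name="spot_id"),
        ),
    )
    truth = GroundTruth(niche_id=pd.Series(niche_id, index=spot_ids))
    return abundance, truth
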