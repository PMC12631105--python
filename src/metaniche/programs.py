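"""Consensus-NMF program discovery and meta-program clustering.

The tumour-heterogeneity workflow runs, per sample:

1. preprocessing — counts-per-10k per cell, selection of the most
   variable genes, per-gene scaling to unit variance (multiplicative, so
   nonnegativity is preserved);
2. consensus NMF at each rank K in a range (default 4..12): many
   randomly initialised NMF replicates, pooling of the replicate spectra,
   removal of outlier spectra by a local-density filter, K-means
   partitioning of the survivors into K clusters, per-cluster median as
   the consensus spectrum, and a nonnegative-least-squares refit of the
   usage matrix;
3. robust-program selection — a program is kept when its top-gene list
   recurs (by overlap count) at another K within the same sample and in
   at least one other sample;
4. greedy meta-program (MP) clustering by gene overlap: clusters are
   seeded with the program of highest summed Jaccard similarity to all
   others and grown by repeatedly absorbing the program with the largest
   overlap with the running signature; the signature is the 30 genes
   shared by the most member programs.  MPs whose members all come from
   one sample are discarded.

MP signatures are annotated against functional gene-set collections with
a hypergeometric upper-tail test and Benjamini-Hochberg correction.

All tie-breaks are deterministic (weight descending, then lexicographic
gene id), so a fixed seed reproduces every output bitwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from statsmodels.stats.multitest import multipletests

from .core_io import ConfigError, CountMatrix, GeneSetCollection


@dataclass
class ProgramSetConfig:
    """Parameters of the per-sample program-discovery stage."""

    k_min: int = 4
    k_max: int = 12
    n_replicates: int = 200
    top_genes_per_program: int = 50
    n_hvg: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ConfigError("k_min must be at least 2")
        if self.k_max < self.k_min:
            raise ConfigError("k_max must be >= k_min")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 NMF replicates")


@dataclass
class GeneProgram:
    """One consensus NMF program with provenance."""

    sample_id: str
    k: int
    program_index: int
    genes: list[str]
    spectrum: np.ndarray
    top_genes: list[str]

    @property
    def top_set(self) -> frozenset:
        return frozenset(self.top_genes)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.k, self.program_index)


@dataclass
class MetaProgram:
    """A cluster of robust programs summarised by a 30-gene signature."""

    mp_id: str
    member_programs: list[GeneProgram]
    signature: list[str]

    @property
    def member_samples(self) -> set:
        return {p.sample_id for p in self.member_programs}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def nmf_preprocess(
    m: CountMatrix, n_hvg: int = 2000
) -> tuple[np.ndarray, list[str]]:
    """Counts-per-10k, top-``n_hvg`` variable genes, unit gene variance.

    Returns a dense cells x genes array (nonnegative) plus the retained
    gene ids.  Genes with zero variance carry no signal for NMF and are
    dropped.
    """
    X = m.counts.astype(float).toarray()  # genes x cells
    colsum = X.sum(axis=0)
    colsum[colsum == 0] = 1.0
    X = X / colsum[None, :] * 1e4
    var = X.var(axis=1)
    keep = np.flatnonzero(var > 0)
    if keep.size == 0:
        raise ConfigError("no gene has nonzero variance")
    if keep.size > n_hvg:
        order = np.argsort(-var[keep], kind="stable")
        keep = np.sort(keep[order[:n_hvg]])
    X = X[keep, :]
    X = X / np.sqrt(X.var(axis=1))[:, None]
    genes = [m.gene_ids[i] for i in keep]
    return X.T.copy(), genes  # cells x genes


def reconstruction_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(X - W @ H, "fro"))


# ---------------------------------------------------------------------------
# consensus NMF
# ---------------------------------------------------------------------------

def _top_genes(spectrum: np.ndarray, genes: list[str], n: int) -> list[str]:
    order = sorted(range(len(genes)), key=lambda i: (-spectrum[i], genes[i]))
    return [genes[i] for i in order[: min(n, len(genes))]]


def consensus_nmf(
    m: CountMatrix,
    k: int,
    n_replicates: int = 200,
    seed: int = 0,
    top_genes_per_program: int = 50,
    n_hvg: int = 2000,
    max_iter: int = 500,
    tol: float = 1e-4,
    density_neighbors: int = 15,
    density_percentile: float = 90.0,
    preprocess: bool = True,
) -> tuple[list[GeneProgram], pd.DataFrame]:
    """Consensus NMF at a single rank ``k`` for one (preprocessed) sample.

    Replicate spectra are L2-normalised and pooled; spectra whose mean
    distance to their ``density_neighbors`` nearest neighbours exceeds
    the ``density_percentile`` of that statistic are treated as outliers
    and removed before K-means clustering.  The consensus spectrum is the
    per-cluster elementwise median; cell usages are re-fit against the
    consensus spectra by nonnegative least squares.
    """
    if preprocess:
        X, genes = nmf_preprocess(m, n_hvg=n_hvg)
    else:
        X, genes = m.counts.astype(float).toarray().T.copy(), list(m.gene_ids)
    n_cells, n_genes = X.shape
    if k >= min(n_cells, n_genes):
        raise ConfigError(f"k={k} must be below min(cells, genes)={min(n_cells, n_genes)}")

    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    pool = []
    with warnings.catch_warnings():
        # reaching max_iter still yields a usable replicate
        warnings.simplefilter("ignore")
        for rs in rep_seeds:
            try:
                model = NMF(
                    n_components=k,
                    init="random",
                    solver="cd",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=int(rs),
                )
                model.fit(X)
                H = model.components_
            except Exception as exc:  # non-convergent / degenerate replicate
                warnings.warn(f"NMF replicate dropped: {exc}")
                continue
            if not np.isfinite(H).all():
                warnings.warn("NMF replicate dropped: non-finite spectrum")
                continue
            norms = np.linalg.norm(H, axis=1)
            norms[norms == 0] = 1.0
            pool.append(H / norms[:, None])
    if not pool:
        raise RuntimeError("every NMF replicate failed")
    spectra = np.vstack(pool)

    # local-density outlier filter on the pooled replicate spectra
    if len(spectra) > k:
        nn = min(density_neighbors, len(spectra) - 1)
        D = cdist(spectra, spectra)
        np.fill_diagonal(D, np.inf)
        knn_mean = np.sort(D, axis=1)[:, :nn].mean(axis=1)
        cutoff = np.percentile(knn_mean, density_percentile)
        keep = knn_mean <= cutoff
        if keep.sum() >= k:
            spectra = spectra[keep]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(spectra)
    consensus = np.vstack(
        [np.median(spectra[labels == c], axis=0) for c in range(k)]
    )
    consensus = np.maximum(consensus, 0.0)

    # usage refit: per cell, nonnegative least squares against consensus
    A = consensus.T  # genes x k
    usage = np.vstack([nnls(A, X[i])[0] for i in range(n_cells)])

    # deterministic program order: total usage desc, then spectrum lexicographic
    order = sorted(
        range(k),
        key=lambda c: (-usage[:, c].sum(), tuple(np.round(consensus[c], 12))),
    )
    consensus = consensus[order]
    usage = usage[:, order]

    programs = [
        GeneProgram(
            sample_id=str(m.cell_meta["sample"].iloc[0]) if m.n_cells else "sample",
            k=k,
            program_index=i,
            genes=genes,
            spectrum=consensus[i],
            top_genes=_top_genes(consensus[i], genes, top_genes_per_program),
        )
        for i in range(k)
    ]
    usage_df = pd.DataFrame(
        usage, index=m.cell_ids, columns=[f"k{k}_p{i}" for i in range(k)]
    )
    return programs, usage_df


def programs_for_sample(
    m: CountMatrix, cfg: ProgramSetConfig
) -> tuple[list[GeneProgram], dict[int, pd.DataFrame]]:
    """Consensus programs for every K in [k_min, k_max] (72 for K=4..12)."""
    ss = np.random.SeedSequence(cfg.seed)
    k_values = list(range(cfg.k_min, cfg.k_max + 1))
    k_seeds = ss.generate_state(len(k_values)) % (2**31)
    all_programs: list[GeneProgram] = []
    usages: dict[int, pd.DataFrame] = {}
    for k, kseed in zip(k_values, k_seeds):
        progs, usage = consensus_nmf(
            m,
            k,
            n_replicates=cfg.n_replicates,
            seed=int(kseed),
            top_genes_per_program=cfg.top_genes_per_program,
            n_hvg=cfg.n_hvg,
        )
        all_programs.extend(progs)
        usages[k] = usage
    return all_programs, usages


# ---------------------------------------------------------------------------
# robust-program selection
# ---------------------------------------------------------------------------

def select_robust(
    programs: list[GeneProgram],
    intra_overlap_min: int = 35,
    inter_overlap_min: int = 10,
) -> list[GeneProgram]:
    """Keep programs recurring across K within their sample and across samples.

    A program survives iff its top-gene list shares at least
    ``intra_overlap_min`` genes with some program of the same sample at a
    different K, and at least ``inter_overlap_min`` genes with some
    program of a different sample.
    """
    samples = {p.sample_id for p in programs}
    if len(samples) < 2:
        warnings.warn(
            "robust-program selection needs programs from at least two samples; "
            "returning an empty list"
        )
        return []
    tops = [p.top_set for p in programs]
    kept = []
    for i, p in enumerate(programs):
        intra = any(
            len(tops[i] & tops[j]) >= intra_overlap_min
            for j, q in enumerate(programs)
            if j != i and q.sample_id == p.sample_id and q.k != p.k
        )
        if not intra:
            continue
        inter = any(
            len(tops[i] & tops[j]) >= inter_overlap_min
            for j, q in enumerate(programs)
            if q.sample_id != p.sample_id
        )
        if inter:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# meta-program clustering
# ---------------------------------------------------------------------------

def jaccard(a, b) -> float:
    """|a∩b| / |a∪b|; two empty sets give 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _signature(
    members: list[GeneProgram], signature_size: int
) -> list[str]:
    """The ``signature_size`` genes occurring in most members' top lists.

    Ties break by summed spectrum weight (descending), then gene id.
    """
    count: dict[str, int] = {}
    weight: dict[str, float] = {}
    for p in members:
        gene_pos = {g: i for i, g in enumerate(p.genes)}
        for g in p.top_genes:
            count[g] = count.get(g, 0) + 1
            weight[g] = weight.get(g, 0.0) + float(p.spectrum[gene_pos[g]])
    ranked = sorted(count, key=lambda g: (-count[g], -weight[g], g))
    return ranked[:signature_size]


def cluster_metaprograms(
    robust: list[GeneProgram],
    min_join_overlap: int = 10,
    signature_size: int = 30,
) -> list[MetaProgram]:
    """Greedy founder clustering of robust programs into meta-programs.

    Repeatedly: seed a cluster with the unassigned program of largest
    summed Jaccard to all other unassigned programs; grow it by adding
    the unassigned program with the largest top-gene overlap with the
    current signature while that overlap is at least
    ``min_join_overlap``; recompute the signature after every addition.
    Clusters whose members all come from a single sample are discarded.
    """
    if not robust:
        raise ConfigError("no robust programs to cluster")
    unassigned = list(robust)
    clusters: list[list[GeneProgram]] = []
    while unassigned:
        sims = [
            (sum(jaccard(p.top_set, q.top_set) for q in unassigned if q is not p), p)
            for p in unassigned
        ]
        sims.sort(key=lambda t: (-t[0], t[1].key))
        founder = sims[0][1]
        members = [founder]
        unassigned.remove(founder)
        signature = _signature(members, signature_size)
        while unassigned:
            # deterministic max: overlap desc then provenance key asc
            best_overlap = max(len(p.top_set & set(signature)) for p in unassigned)
            cands = [p for p in unassigned if len(p.top_set & set(signature)) == best_overlap]
            cand = min(cands, key=lambda p: p.key)
            if best_overlap < min_join_overlap:
                break
            members.append(cand)
            unassigned.remove(cand)
            signature = _signature(members, signature_size)
        clusters.append(members)

    mps = []
    n = 0
    for members in clusters:
        if len({p.sample_id for p in members}) < 2:
            continue
        n += 1
        sig = _signature(members, signature_size)
        if len(sig) < signature_size:
            warnings.warn(
                f"meta-program MP{n}: only {len(sig)} distinct genes available; "
                "signature truncated"
            )
        mps.append(MetaProgram(mp_id=f"MP{n}", member_programs=members, signature=sig))
    return mps


# ---------------------------------------------------------------------------
# MP annotation
# ---------------------------------------------------------------------------

def annotate_mp(
    mp: MetaProgram, sets: GeneSetCollection, universe_size: int
) -> pd.DataFrame:
    """Hypergeometric enrichment of the MP signature in each gene set.

    p = P(X >= overlap) with X ~ Hypergeom(universe_size, |set|,
    |signature|); a Benjamini-Hochberg adjusted column is attached.
    Signature genes outside a declared universe are counted out.
    """
    sig = list(mp.signature)
    if sets.universe is not None:
        universe = set(sets.universe)
        dropped = [g for g in sig if g not in universe]
        if dropped:
            warnings.warn(
                f"{len(dropped)} signature genes absent from the universe; ignored"
            )
            sig = [g for g in sig if g in universe]
    draw = len(sig)
    if universe_size < max((len(s) for s in sets.sets.values()), default=0):
        raise ConfigError("universe_size smaller than the largest gene set")
    rows = []
    for name, members in sets.sets.items():
        overlap = len(set(sig) & set(members))
        p = float(hypergeom.sf(overlap - 1, universe_size, len(members), draw))
        rows.append({"set_name": name, "set_size": len(members), "overlap": overlap, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
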