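"""Per-cell signature scoring, pseudobulk, subtype calls and the
four-gene MHC-II gate.

Two scoring schemes are provided:

* ``module_score`` — the control-gene module score: mean log-normalised
  expression of the signature minus the mean of expression-bin-matched
  control genes, per cell.  Genes are binned into equal-frequency bins
  by mean expression; each signature gene contributes ``n_ctrl`` control
  genes drawn from its own bin.

* ``rank_auc`` — a rank-based recovery score: genes are ranked per cell
  by expression (descending) and the score is the area under the
  recovery curve of the gene set within the top fraction of the ranking,
  normalised to [0, 1] by the maximal achievable area.  The score is
  invariant under any strictly monotone transform of the expression
  values within a cell.

Muscle-invasive samples are called luminal or basal by comparing the
per-sample mean rank-AUC of the two subtype gene sets — a score
comparison, not a re-implementation of the published nearest-centroid
classifier.

A cancer cell is MHC-II positive when it has detectable (count > 0)
expression of all four of HLA-DRA, HLA-DRB1, HLA-DPA1 and HLA-DPB1;
the gate is evaluated on raw counts, which is equivalent to any
zero-preserving normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ConfigError, CountMatrix

MHC2_DEFAULT_GENES = ("HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1")


@dataclass
class SignatureScore:
    name: str
    method: str  # "module" | "rank_auc"
    values: pd.Series  # per cell


@dataclass
class MHC2Call:
    positive: pd.Series  # bool per cell
    genes: tuple[str, ...]
    fraction_by_sample: pd.Series


def log_normalize(m: CountMatrix) -> np.ndarray:
    """log1p of counts-per-10k; dense genes x cells."""
    X = m.counts.astype(float).toarray()
    colsum = X.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return np.log1p(X / colsum[None, :] * 1e4)


def _bin_genes(means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bins on gene mean expression; ties take the lower bin."""
    G = len(means)
    order = np.argsort(means, kind="stable")
    bins = np.empty(G, dtype=int)
    bins[order] = np.arange(G) * n_bins // G
    # ties share the lowest bin among their positions
    s = pd.Series(bins).groupby(pd.Series(means)).transform("min")
    return s.to_numpy()


def module_score(
    m: CountMatrix,
    signature: list[str],
    name: str = "signature",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureScore:
    """Control-gene module score on log-normalised expression.

    Control genes are drawn from the signature gene's expression bin —
    without replacement when the bin holds at least ``n_ctrl`` genes,
    with replacement otherwise.  The control average is taken over the
    pooled draw with multiplicity.
    """
    X = log_normalize(m)
    present = [g for g in signature if g in m.gene_ids]
    dropped = set(signature) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} signature genes absent from matrix; dropped")
    if not present:
        raise ConfigError("signature is empty after filtering to matrix genes")
    gene_idx = {g: i for i, g in enumerate(m.gene_ids)}
    sig_idx = np.array([gene_idx[g] for g in present])

    means = X.mean(axis=1)
    bins = _bin_genes(means, min(n_bins, m.n_genes))
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        replace = len(pool) < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)

    score = X[sig_idx].mean(axis=0) - X[ctrl].mean(axis=0)
    return SignatureScore(
        name=name, method="module", values=pd.Series(score, index=m.cell_ids)
    )


def rank_auc(
    m: CountMatrix,
    gene_set: list[str],
    name: str = "signature",
    top_fraction: float = 0.05,
    seed: int = 0,
) -> SignatureScore:
    """Recovery-curve AUC of ``gene_set`` in each cell's expression ranking.

    With threshold T = ceil(top_fraction * G), the recovery curve counts
    set genes among the top x ranks for x = 1..T; the score is the step
    integral of that curve divided by its maximum achievable value.  Ties
    in expression break by gene order after one seeded shuffle of the
    gene axis, fixed for the whole run.
    """
    if not (0 < top_fraction <= 1):
        raise ConfigError("top_fraction must be in (0, 1]")
    present = [g for g in gene_set if g in m.gene_ids]
    if not present:
        raise ConfigError("gene_set shares no genes with the matrix")
    G = m.n_genes
    T = int(np.ceil(top_fraction * G))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(G)

    X = m.counts.astype(float).toarray()[perm, :]
    in_set = np.zeros(G, dtype=bool)
    gene_idx = {g: i for i, g in enumerate(m.gene_ids)}
    in_set[[gene_idx[g] for g in present]] = True
    in_set = in_set[perm]

    n_set = len(present)
    max_area = np.minimum(np.arange(1, T + 1), n_set).sum()
    scores = np.empty(m.n_cells)
    for c in range(m.n_cells):
        order = np.argsort(-X[:, c], kind="stable")
        hits = in_set[order[:T]]
        recovery = np.cumsum(hits)
        scores[c] = recovery.sum() / max_area
    return SignatureScore(
        name=name, method="rank_auc", values=pd.Series(scores, index=m.cell_ids)
    )


def pseudobulk(m: CountMatrix, by: str = "sample") -> pd.DataFrame:
    """Gene-wise count sums per group of cells; genes x groups."""
    if by not in m.cell_meta.columns:
        raise ConfigError(f"unknown grouping column {by!r}")
    groups = m.cell_meta[by]
    out = {}
    for g in pd.unique(groups):
        cols = np.flatnonzero((groups == g).to_numpy())
        out[g] = np.asarray(m.counts[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=m.gene_ids)


def call_luminal_basal(
    scores_basal: pd.Series, scores_luminal: pd.Series
) -> pd.DataFrame:
    """Per-sample basal/luminal call by score comparison, with margin."""
    samples = scores_basal.index
    if not samples.equals(scores_luminal.index):
        raise ConfigError("basal and luminal scores must cover the same samples")
    margin = scores_basal - scores_luminal
    label = pd.Series(
        np.where(margin > 0, "basal", np.where(margin < 0, "luminal", "indeterminate")),
        index=samples,
    )
    return pd.DataFrame({"label": label, "margin": margin})


def mhc2_gate(
    m: CountMatrix, genes: tuple[str, ...] = MHC2_DEFAULT_GENES
) -> MHC2Call:
    """Classify cells MHC-II positive when all four gate genes have count > 0."""
    if len(genes) != 4:
        raise ConfigError("the MHC-II gate uses exactly four genes")
    idx = []
    for g in genes:
        if g not in m.gene_ids:
            raise KeyError(f"gate gene {g!r} not present in the matrix")
        idx.append(m.gene_ids.index(g))
    sub = m.counts[idx, :].toarray()
    positive = pd.Series((sub > 0).all(axis=0), index=m.cell_ids)
    frac = positive.groupby(m.cell_meta["sample"]).mean()
    return MHC2Call(positive=positive, genes=tuple(genes), fraction_by_sample=frac)
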