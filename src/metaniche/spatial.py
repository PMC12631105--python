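"""Spatial colocalization of cell types on spot grids.

Works on spot x cell-type abundance tables (as produced upstream by spot
deconvolution).  Each cell type's abundances over spots are normalised to
a probability distribution; pairwise spatial similarity is the symmetric
Kullback-Leibler divergence

    sKL(p, q) = 1/2 [ KL(p || q) + KL(q || p) ]

in nats — low sKL means the two cell types occupy the same spots.  A
subsampling null is attached: each replicate independently draws 80% of
the spots for each of the two cell types, renormalises both abundance
vectors on the intersection of the two draws, and recomputes sKL; the
empirical p-value is the fraction of null values strictly exceeding the
observed one.  This null measures the stability of the observed sKL
under spot subsampling rather than a classical independence null; it is
implemented verbatim, and the interpretation is documented rather than
altered.

NMF on the spot x cell-type matrix summarises co-occurrence: cell types
loading on the same factor share spatial compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .core_io import ConfigError, FormatError

# Relative pseudocount keeping KL finite when some spots have zero abundance.
DEFAULT_PSEUDOCOUNT_SCALE = 1e-9


@dataclass
class SpotAbundance:
    """Spots x cell-type nonnegative abundances with grid coordinates."""

    abundances: pd.DataFrame  # index: spot_id, columns: cell types
    coordinates: pd.DataFrame  # index: spot_id, columns: row, col
    slide_id: str = "slide0"

    def __post_init__(self) -> None:
        if self.abundances.index.has_duplicates:
            raise FormatError("duplicate spot ids")
        vals = self.abundances.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise FormatError("abundances must be finite and nonnegative")
        if not self.coordinates.index.equals(self.abundances.index):
            self.coordinates = self.coordinates.reindex(self.abundances.index)

    @property
    def n_spots(self) -> int:
        return len(self.abundances)

    @property
    def celltypes(self) -> list[str]:
        return list(self.abundances.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.coordinates.join(self.abundances)
        out.insert(0, "spot_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, slide_id: str = "slide0") -> "SpotAbundance":
        df = pd.read_csv(path, sep="\t").set_index("spot_id")
        coords = df[["row", "col"]]
        ab = df.drop(columns=["row", "col"])
        return cls(abundances=ab, coordinates=coords, slide_id=slide_id)


@dataclass
class ColocalizationResult:
    """Observed sKL, its subsampling null and the empirical p-value."""

    type1: str
    type2: str
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    subsample_fraction: float
    seed: int
    add_one: bool = False


def to_distribution(
    a: SpotAbundance, celltype: str, pseudocount: float | None = None
) -> np.ndarray:
    """Normalise one cell type's spot abundances to a probability vector.

    ``pseudocount=None`` uses ``1e-9 * mean abundance`` of that cell type
    so the result is strictly positive wherever any signal exists.
    """
    if celltype not in a.abundances.columns:
        raise KeyError(f"cell type {celltype!r} not in abundance table")
    vec = a.abundances[celltype].to_numpy(dtype=float)
    return _normalize(vec, pseudocount)


def _normalize(vec: np.ndarray, pseudocount: float | None) -> np.ndarray:
    if pseudocount is None:
        pseudocount = DEFAULT_PSEUDOCOUNT_SCALE * (vec.mean() if vec.mean() > 0 else 1.0)
    shifted = vec + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector with zero pseudocount")
    return shifted / total


def symmetric_kl(p: np.ndarray, q: np.ndarray) -> float:
    """1/2 [KL(p||q) + KL(q||p)] in nats for strictly positive p, q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"support mismatch: {p.shape} vs {q.shape}")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("distributions must be strictly positive; use a pseudocount")
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def coloc_permutation(
    a: SpotAbundance,
    type1: str,
    type2: str,
    n_perm: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    pseudocount: float | None = None,
    add_one: bool = False,
) -> ColocalizationResult:
    """Observed sKL between two cell types plus an 80%-subsampling null.

    Each of ``n_perm`` replicates draws, independently for the two cell
    types and without replacement, ``ceil(frac * n_spots)`` spots,
    restricts both abundance vectors to the intersection of the draws,
    renormalises, and records sKL.  Empirical p = (# null > observed) /
    n_perm; with ``add_one`` the (b+1)/(n+1) variant is used so p can
    never be exactly zero.
    """
    if a.n_spots < 5:
        raise ConfigError("need at least 5 spots for the subsampling null")
    if not (0 < frac <= 1):
        raise ConfigError("frac must be in (0, 1]")
    v1 = a.abundances[type1].to_numpy(dtype=float)
    v2 = a.abundances[type2].to_numpy(dtype=float)
    observed = symmetric_kl(_normalize(v1, pseudocount), _normalize(v2, pseudocount))

    rng = np.random.default_rng(seed)
    n = a.n_spots
    k = int(np.ceil(frac * n))
    null = np.empty(n_perm)
    redraws = 0
    i = 0
    while i < n_perm:
        s1 = rng.choice(n, size=k, replace=False)
        s2 = rng.choice(n, size=k, replace=False)
        inter = np.intersect1d(s1, s2)
        if inter.size == 0:
            redraws += 1
            if redraws > n_perm:
                raise RuntimeError("subsample intersection repeatedly empty")
            warnings.warn("empty subsample intersection; redrawing")
            continue
        null[i] = symmetric_kl(
            _normalize(v1[inter], pseudocount), _normalize(v2[inter], pseudocount)
        )
        i += 1
    exceed = int((null > observed).sum())
    p = (exceed + 1) / (n_perm + 1) if add_one else exceed / n_perm
    return ColocalizationResult(
        type1=type1,
        type2=type2,
        observed=observed,
        null_values=null,
        p_value=float(p),
        n_perm=n_perm,
        subsample_fraction=frac,
        seed=seed,
        add_one=add_one,
    )


def coloc_all_pairs(
    a: SpotAbundance,
    n_perm: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    pseudocount: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ColocalizationResult]]:
    """Pairwise sKL and empirical-p matrices over all cell-type pairs."""
    types = a.celltypes
    skl = pd.DataFrame(0.0, index=types, columns=types)
    pmat = pd.DataFrame(np.nan, index=types, columns=types)
    results = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(types) * len(types)) % (2**31)
    for i, t1 in enumerate(types):
        for j, t2 in enumerate(types):
            if j <= i:
                continue
            res = coloc_permutation(
                a,
                t1,
                t2,
                n_perm=n_perm,
                frac=frac,
                seed=int(child_seeds[i * len(types) + j]),
                pseudocount=pseudocount,
            )
            skl.loc[t1, t2] = skl.loc[t2, t1] = res.observed
            pmat.loc[t1, t2] = pmat.loc[t2, t1] = res.p_value
            results.append(res)
    return skl, pmat, results


def compartment_nmf(
    a: SpotAbundance, n_factors: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NMF of spots x cell-type abundances into co-occurrence compartments.

    Returns (spot loadings, cell-type weights); weights are scaled so each
    factor's maximum is 1, the conventional display normalisation.
    """
    X = a.abundances.to_numpy(dtype=float)
    n_types = X.shape[1]
    if n_factors >= n_types:
        raise ConfigError(
            f"n_factors ({n_factors}) must be below the number of cell types ({n_types})"
        )
    model = NMF(
        n_components=n_factors,
        init="random",
        random_state=seed,
        max_iter=2000,
        tol=1e-6,
    )
    W = model.fit_transform(X)
    H = model.components_
    factor_names = [f"factor{i + 1}" for i in range(n_factors)]
    loadings = pd.DataFrame(W, index=a.abundances.index, columns=factor_names)
    scale = H.max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    weights = pd.DataFrame(H / scale, index=factor_names, columns=a.celltypes)
    return loadings, weights
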