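"""Binned Hi-C contact matrices: binning, pooling, balancing, QC.

Conventions
-----------
Bins are 0-based half-open internally and tile each chromosome at a fixed
bin size (the last bin may be short).  The contact matrix is stored as a
full symmetric sparse matrix in which off-diagonal cell (i, j) holds the
number of valid pairs linking bins i and j and diagonal cell (i, i) holds
twice the number of intra-bin pairs, so that any block sum equals twice
the number of pairs in the block; this makes aggregation across
resolutions exact.  ``depth`` is the number of pairs, i.e. half the matrix
total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .layout import GenomeLayout

DEFAULT_RESOLUTIONS = (500_000, 200_000, 100_000, 40_000, 20_000, 10_000, 5_000)

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


class ConvergenceError(RuntimeError):
    """Iterative balancing failed to reach the requested tolerance."""


def make_bins(layout: GenomeLayout, binsize: int) -> pd.DataFrame:
    """Tile every chromosome with ``binsize`` bins (last bin may be short)."""
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    rows = []
    for name, length, _ in layout.chroms:
        starts = np.arange(0, length, binsize, dtype=np.int64)
        ends = np.minimum(starts + binsize, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    return bins


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix with an attached bin table."""

    bins: pd.DataFrame
    counts: sp.csr_matrix
    binsize: int
    balanced: bool = False
    bias: np.ndarray | None = None
    mask: np.ndarray | None = None
    layout: GenomeLayout | None = None

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin table")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def depth(self) -> float:
        """Total number of pairs represented (half the matrix sum)."""
        return float(self.counts.sum()) / 2.0

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def marginals(self) -> np.ndarray:
        """Per-bin contact ends (row sums; intra-bin pairs count twice)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def same_bins(self, other: "ContactMatrix") -> bool:
        if self.binsize != other.binsize or self.n_bins != other.n_bins:
            return False
        a, b = self.bins, other.bins
        return bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 1-based genomic position."""
        sl = self.chrom_slice(chrom)
        return sl.start + (pos - 1) // self.binsize

    def bin_distance_matrix(self, chrom: str) -> np.ndarray:
        """Circular genomic distances (bp) between bin starts of one chromosome."""
        sl = self.chrom_slice(chrom)
        starts = self.bins["start"].to_numpy()[sl]
        d = np.abs(starts[:, None] - starts[None, :])
        if self.layout is not None and self.layout.is_circular(chrom):
            L = self.layout.length(chrom)
            d = np.minimum(d, L - d)
        return d


def _require_same_bins(a: ContactMatrix, b: ContactMatrix) -> None:
    if a.binsize != b.binsize or len(a.bins) != len(b.bins):
        raise ValueError("bin tables differ in size or bin size")
    cols = a.bins[["chrom", "start", "end"]].to_numpy()
    colsb = b.bins[["chrom", "start", "end"]].to_numpy()
    neq = np.nonzero(~(cols == colsb).all(axis=1))[0]
    if neq.size:
        i = int(neq[0])
        raise ValueError(f"bin tables differ first at bin {i}: {tuple(cols[i])} vs {tuple(colsb[i])}")


def bin_pairs(pairs: pd.DataFrame, layout: GenomeLayout, binsize: int) -> ContactMatrix:
    """Bin a valid-pairs table into a symmetric contact matrix.

    ``pairs`` needs columns ``chrom1, pos1, chrom2, pos2`` (1-based
    positions); strand columns are accepted and ignored.  Each pair
    increments cell ``(bin(pos1), bin(pos2))`` and its mirror, so the
    resulting depth equals the number of pairs.
    """
    bins = make_bins(layout, binsize)
    n = len(bins)
    offsets: dict[str, int] = {}
    nbins_of: dict[str, int] = {}
    for name in layout.names:
        idx = np.flatnonzero((bins["chrom"] == name).to_numpy())
        offsets[name] = int(idx[0])
        nbins_of[name] = int(idx.size)

    def to_bins(chrom_col: str, pos_col: str) -> np.ndarray:
        chroms = pairs[chrom_col].to_numpy()
        pos = pairs[pos_col].to_numpy(dtype=np.int64)
        unknown = ~np.isin(chroms, layout.names)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise ValueError(
                f"pair row {row} references unknown chromosome {chroms[row]!r}: "
                f"{pairs.iloc[row].to_dict()}"
            )
        out = np.empty(len(pairs), dtype=np.int64)
        for name in layout.names:
            m = chroms == name
            if not m.any():
                continue
            L = layout.length(name)
            p = pos[m]
            if ((p < 1) | (p > L)).any():
                bad = int(np.flatnonzero(m)[np.flatnonzero((p < 1) | (p > L))[0]])
                raise ValueError(f"pair row {bad}: position outside chromosome {name!r}")
            b = (p - 1) // binsize
            out[m] = offsets[name] + np.minimum(b, nbins_of[name] - 1)
        return out

    bi = to_bins("chrom1", "pos1")
    bj = to_bins("chrom2", "pos2")
    flat = np.bincount(bi * n + bj, minlength=n * n).reshape(n, n)
    mat = sp.csr_matrix(flat + flat.T)
    return ContactMatrix(bins=bins, counts=mat, binsize=binsize, layout=layout)


def pool_replicates(mats: list[ContactMatrix]) -> ContactMatrix:
    """Cell-wise sum of replicate matrices sharing one bin table."""
    if not mats:
        raise ValueError("no matrices to pool")
    first = mats[0]
    total = first.counts.copy()
    for other in mats[1:]:
        if other.balanced or first.balanced:
            raise ValueError("pooling requires unbalanced matrices")
        _require_same_bins(first, other)
        total = total + other.counts
    return ContactMatrix(
        bins=first.bins.copy(),
        counts=sp.csr_matrix(total),
        binsize=first.binsize,
        layout=first.layout,
    )


def aggregate(mat: ContactMatrix, factor: int) -> ContactMatrix:
    """Coarsen a matrix by summing ``factor``-sized blocks of bins per chromosome."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if mat.layout is None:
        raise ValueError("aggregation requires a layout")
    new = make_bins(mat.layout, mat.binsize * factor)
    groups = np.empty(mat.n_bins, dtype=np.int64)
    for name in mat.layout.names:
        sl = mat.chrom_slice(name)
        off_new = int(np.flatnonzero((new["chrom"] == name).to_numpy())[0])
        local = np.arange(sl.stop - sl.start) // factor
        groups[sl] = off_new + local
    m = len(new)
    P = np.zeros((mat.n_bins, m))
    P[np.arange(mat.n_bins), groups] = 1.0
    agg = P.T @ mat.dense() @ P
    return ContactMatrix(bins=new, counts=sp.csr_matrix(agg), binsize=mat.binsize * factor, layout=mat.layout)


def ice_normalize(
    mat: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 300,
    mask_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative correction (ICE) of multiplicative per-bin biases.

    Repeatedly divides the matrix by its row/column marginals until the
    coefficient of variation of the non-masked marginals drops below
    ``tol``.  Bins whose raw marginal falls in the lowest ``mask_frac``
    quantile (or is zero) are masked out.  The balanced matrix is rescaled
    to preserve the raw depth of the unmasked submatrix, and the returned
    object carries the accumulated bias vector ``b`` such that
    ``balanced[i, j] == raw[i, j] / (b[i] * b[j])`` (NaN on masked bins).
    """
    if mat.balanced:
        raise ValueError("matrix is already balanced")
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = mat.dense()
    total = M.sum()
    if total == 0:
        raise ValueError("cannot balance an all-zero matrix")
    marg = M.sum(axis=1)
    cutoff = np.quantile(marg, mask_frac) if mask_frac > 0 else -np.inf
    mask = (marg <= cutoff) | (marg == 0)
    if mask.all():
        raise ValueError("all bins masked; lower mask_frac")
    W = M.copy()
    W[mask, :] = 0.0
    W[:, mask] = 0.0
    kept_total = W.sum()
    if kept_total == 0:
        raise ValueError("masking removed all contacts")
    n = mat.n_bins
    bias = np.ones(n)
    cv = np.inf
    for _ in range(max_iter):
        s = W.sum(axis=1)
        live = s[~mask]
        mean = live.mean()
        cv = live.std() / mean
        if cv < tol:
            break
        f = s / mean
        f[mask | (s == 0)] = 1.0
        W /= np.outer(f, f)
        bias *= f
    else:
        raise ConvergenceError(f"ICE did not converge after {max_iter} iterations (CV={cv:.3g})")
    scale = kept_total / W.sum()
    W *= scale
    bias = bias / np.sqrt(scale)
    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return ContactMatrix(
        bins=mat.bins.copy(),
        counts=sp.csr_matrix(W),
        binsize=mat.binsize,
        balanced=True,
        bias=bias_out,
        mask=mask,
        layout=mat.layout,
    )


def replicate_concordance(a: ContactMatrix, b: ContactMatrix, max_dist: int) -> float:
    """Distance-stratified replicate concordance in [-1, 1].

    For every intra-chromosomal genomic distance up to ``max_dist`` the
    Pearson correlation between the two matrices' cells at that distance is
    computed (strata without variance are skipped) and the strata are
    combined as a depth-weighted mean, weighting each stratum by its total
    contact count in the two matrices.  Inter-chromosomal cells carry no
    genomic distance and are excluded.
    """
    _require_same_bins(a, b)
    if max_dist < a.binsize:
        raise ValueError("max_dist must be at least one bin size")
    if a.layout is None:
        raise ValueError("concordance requires a layout on the first matrix")
    A, B = a.dense(), b.dense()
    scores: list[float] = []
    weights: list[float] = []
    for name in a.layout.names:
        sl = a.chrom_slice(name)
        d = a.bin_distance_matrix(name)
        sub_a, sub_b = A[sl, sl], B[sl, sl]
        iu = np.triu_indices(sl.stop - sl.start, k=1)
        dv, av, bv = d[iu], sub_a[iu], sub_b[iu]
        keep = dv <= max_dist
        dv, av, bv = dv[keep], av[keep], bv[keep]
        for dist in np.unique(dv):
            m = dv == dist
            x, y = av[m], bv[m]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            scores.append(r)
            weights.append(float(x.sum() + y.sum()))
    if len(scores) < 2:
        raise ValueError("fewer than 2 usable distance strata")
    w = np.asarray(weights)
    if w.sum() == 0:
        w = np.ones_like(w)
    return float(np.average(scores, weights=w))


@dataclass
class ResolutionResult:
    """Outcome of the map-resolution criterion."""

    binsize: int
    qualified: bool
    fractions: dict[int, float]


def map_resolution(
    pairs: pd.DataFrame,
    layout: GenomeLayout,
    candidate_binsizes: list[int] | tuple[int, ...] = DEFAULT_RESOLUTIONS,
    min_contacts: int = 1000,
    min_fraction: float = 0.8,
) -> ResolutionResult:
    """Smallest bin size at which >= 80% of loci have >= 1,000 contacts.

    Candidates are evaluated in ascending order; if none qualifies the
    largest candidate is returned with ``qualified=False``.
    """
    if not len(candidate_binsizes):
        raise ValueError("candidate list is empty")
    cands = sorted(int(c) for c in candidate_binsizes)
    fractions: dict[int, float] = {}
    best: int | None = None
    for bs in cands:
        mat = bin_pairs(pairs, layout, bs)
        frac = float((mat.marginals() >= min_contacts).mean())
        fractions[bs] = frac
        if best is None and frac >= min_fraction:
            best = bs
    if best is not None:
        return ResolutionResult(binsize=best, qualified=True, fractions=fractions)
    warnings.warn(
        "no candidate bin size reaches the map-resolution criterion; "
        "returning the largest candidate",
        stacklevel=2,
    )
    return ResolutionResult(binsize=cands[-1], qualified=False, fractions=fractions)


def probability_matrix(mat: ContactMatrix) -> np.ndarray:
    """Dense matrix rescaled to total 1 (contact probability per cell)."""
    M = mat.dense()
    t = M.sum()
    if t == 0:
        raise ValueError("empty matrix")
    return M / t
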