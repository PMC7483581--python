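"""1D/2D structural summaries of bacterial contact maps.

Directionality index (DI) and CID border calling, FIRE-like local
interaction z-scores, log2 differential maps between two samples, and
region-level differential scoring.  All windowed operators wrap around
circular chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, _require_same_bins


@dataclass
class Track:
    """Per-bin 1D signal aligned to a contact matrix's bin table."""

    bins: pd.DataFrame
    values: np.ndarray
    kind: str
    binsize: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bins):
            raise ValueError("track length must equal bin count")

    def chrom_values(self, chrom: str) -> np.ndarray:
        sel = (self.bins["chrom"] == chrom).to_numpy()
        return self.values[sel]


@dataclass
class DifferentialRegion:
    """Run of bins with a consistent differential-contact sign."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    mean_log2: float
    direction: str  # "up" | "down"
    n_bins: int


@dataclass
class DifferentialMap:
    """Cell-wise log2 ratio of two probability-rescaled contact maps."""

    bins: pd.DataFrame
    values: np.ndarray  # dense, NaN where undefined
    binsize: int
    pseudocount: float
    layout: object = None


def _window_indices(n: int, width: int, circular: bool):
    """Index arrays (n x width) of upstream and downstream windows."""
    i = np.arange(n)[:, None]
    up = i - np.arange(width, 0, -1)[None, :]
    down = i + np.arange(1, width + 1)[None, :]
    if circular:
        return up % n, down % n, None, None
    up_valid = up >= 0
    down_valid = down < n
    return np.clip(up, 0, n - 1), np.clip(down, 0, n - 1), up_valid, down_valid


def _impute_masked_by_distance(C: np.ndarray, sub_mask: np.ndarray, circular: bool) -> np.ndarray:
    """Replace cells in masked columns with the mean live cell at the same
    genomic (bin) distance, so windowed sums stay unbiased near masked bins."""
    if not sub_mask.any():
        return C
    n = C.shape[0]
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    if circular:
        d = np.minimum(d, n - d)
    out = C.copy()
    live_cols = ~sub_mask
    for dist in np.unique(d[:, sub_mask]):
        cells = d == dist
        live_cells = cells & live_cols[None, :] & live_cols[:, None]
        fill = C[live_cells].mean() if live_cells.any() else 0.0
        target = cells & (sub_mask[None, :] | sub_mask[:, None])
        out[target] = fill
    return out


def directionality_index(mat: ContactMatrix, scale: int = 100_000) -> Track:
    """Signed chi-squared directionality statistic per bin.

    ``A`` sums contacts from a bin to its upstream window of length
    ``scale`` and ``B`` to its downstream window; with ``E = (A + B) / 2``
    the statistic is ``sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)``
    (0 when A == B == 0).  Windows wrap on circular chromosomes.  Masked
    bins get NaN.
    """
    if scale < mat.binsize:
        raise ValueError("scale must be at least one bin size")
    if scale % mat.binsize:
        raise ValueError("scale must be a multiple of the bin size")
    if mat.layout is None:
        raise ValueError("DI requires a layout")
    width = scale // mat.binsize
    dense = mat.dense()
    mask = mat.mask
    values = np.full(mat.n_bins, np.nan)
    for name in mat.layout.names:
        sl = mat.chrom_slice(name)
        C = dense[sl, sl].copy()
        sub_mask = mask[sl]
        # masked partner cells are imputed at the per-distance mean of live
        # cells: dropping them (or imputing flat) biases one window whenever
        # masked bins cluster, faking border signatures
        C = _impute_masked_by_distance(C, sub_mask, mat.layout.is_circular(name))
        n = C.shape[0]
        up, down, upv, downv = _window_indices(n, min(width, n - 1), mat.layout.is_circular(name))
        rows = np.arange(n)[:, None]
        a_terms = C[rows, up]
        b_terms = C[rows, down]
        if upv is not None:
            a_terms = np.where(upv, a_terms, 0.0)
            b_terms = np.where(downv, b_terms, 0.0)
        A = a_terms.sum(axis=1)
        B = b_terms.sum(axis=1)
        E = (A + B) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            di = np.sign(B - A) * ((A - E) ** 2 + (B - E) ** 2) / E
        di[(A == B)] = 0.0
        di[sub_mask] = np.nan
        values[sl] = di
    return Track(bins=mat.bins.copy(), values=values, kind="DI", binsize=mat.binsize)


def call_cid_borders(di: Track, min_amplitude: float | None = None) -> list[tuple[str, int]]:
    """CID borders at negative-to-positive DI sign changes.

    A crossing between consecutive unmasked bins is a border when the DI
    extrema of the adjacent negative and positive runs both exceed
    ``min_amplitude``.  Away from borders the DI of a count-scale matrix
    behaves like a signed chi-squared statistic with two degrees of
    freedom (magnitude O(1) whatever the depth), so the default gate is
    the 0.999 chi2(2) quantile, ~13.8.  Returns ``(chrom, 1-based start
    of the first bin of the new domain)`` tuples.
    """
    finite = np.isfinite(di.values)
    if not finite.any():
        raise ValueError("DI track is entirely NaN/masked")
    if min_amplitude is None:
        from scipy.stats import chi2

        min_amplitude = float(chi2.ppf(0.999, df=2))
    borders: list[tuple[str, int]] = []
    for chrom in di.bins["chrom"].unique():
        sel = np.flatnonzero((di.bins["chrom"] == chrom).to_numpy())
        v = di.values[sel]
        starts = di.bins["start"].to_numpy()[sel]
        live = np.flatnonzero(np.isfinite(v))
        if live.size < 2:
            continue
        vv = v[live]
        n = live.size
        for k in range(n):
            nxt = (k + 1) % n
            if not (vv[k] < 0 < vv[nxt]):
                continue
            # amplitude of the flanking negative run (left) and positive run (right)
            neg_min = vv[k]
            j = k
            while True:
                jprev = (j - 1) % n
                if jprev == k or vv[jprev] >= 0:
                    break
                neg_min = min(neg_min, vv[jprev])
                j = jprev
            pos_max = vv[nxt]
            j = nxt
            while True:
                jnext = (j + 1) % n
                if jnext == nxt or vv[jnext] <= 0:
                    break
                pos_max = max(pos_max, vv[jnext])
                j = jnext
            if abs(neg_min) > min_amplitude and pos_max > min_amplitude:
                borders.append((str(chrom), int(starts[live[nxt]]) + 1))
    return borders


def fire_score(mat: ContactMatrix, window: int = 10_000) -> Track:
    """Local-interaction (FIRE-like) z-score per bin.

    Raw score is the sum of contacts to bins within ``window`` upstream
    and downstream (self excluded), z-transformed per chromosome over
    unmasked bins.  A chromosome with zero variance yields zeros.
    """
    if window < mat.binsize:
        raise ValueError("window must be at least one bin size")
    if mat.layout is None:
        raise ValueError("FIRE scoring requires a layout")
    width = window // mat.binsize
    dense = mat.dense()
    mask = mat.mask
    values = np.full(mat.n_bins, np.nan)
    for name in mat.layout.names:
        sl = mat.chrom_slice(name)
        C = dense[sl, sl].copy()
        sub_mask = mask[sl]
        C = _impute_masked_by_distance(C, sub_mask, mat.layout.is_circular(name))
        n = C.shape[0]
        up, down, upv, downv = _window_indices(n, min(width, n - 1), mat.layout.is_circular(name))
        rows = np.arange(n)[:, None]
        a = C[rows, up]
        b = C[rows, down]
        if upv is not None:
            a = np.where(upv, a, 0.0)
            b = np.where(downv, b, 0.0)
        raw = a.sum(axis=1) + b.sum(axis=1)
        raw[sub_mask] = np.nan
        live = raw[~sub_mask]
        sd = live.std()
        if sd == 0:
            z = np.where(sub_mask, np.nan, 0.0)
        else:
            z = (raw - live.mean()) / sd
        values[sl] = z
    return Track(bins=mat.bins.copy(), values=values, kind="FIRE_Z", binsize=mat.binsize)


def differential_map(
    a: ContactMatrix, b: ContactMatrix, pseudocount: float | None = None
) -> DifferentialMap:
    """Cell-wise ``log2((B + pc) / (A + pc))`` of probability-rescaled maps.

    Each matrix is rescaled to total 1 before the ratio, making the map
    depth-invariant; the default pseudocount is ``1 / (2 * min depth)``.
    Cells where both matrices are zero, or touching a masked bin of
    either matrix, are NaN.

    Comparing raw (depth-normalized) matrices is recommended for
    sample-versus-sample contrasts: iterative correction equalizes
    per-bin visibility and therefore cancels exactly the per-locus
    depletion signals such contrasts look for.  Balanced inputs are
    accepted for contrasts of internal structure.
    """
    _require_same_bins(a, b)
    if pseudocount is None:
        depths = [d for d in (a.depth, b.depth) if d > 0]
        if not depths:
            raise ValueError("both matrices are empty")
        pseudocount = 1.0 / (2.0 * min(depths))
    A = a.dense()
    B = b.dense()
    PA = A / A.sum()
    PB = B / B.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((PB + pseudocount) / (PA + pseudocount))
    undefined = (A == 0) & (B == 0)
    values[undefined] = np.nan
    masked = (a.mask | b.mask) if a.mask is not None else None
    if masked is not None and masked.any():
        values[masked, :] = np.nan
        values[:, masked] = np.nan
    return DifferentialMap(
        bins=a.bins.copy(),
        values=values,
        binsize=a.binsize,
        pseudocount=pseudocount,
        layout=a.layout,
    )


def differential_regions(
    diff: DifferentialMap, threshold: float = 0.3, min_run: int = 3
) -> list[DifferentialRegion]:
    """Maximal runs of bins whose mean log2-ratio crosses a threshold.

    The per-bin marginal is the mean of the bin's log2-ratio row over
    defined cells; runs of at least ``min_run`` consecutive bins with
    marginal <= -threshold ("down") or >= +threshold ("up") become
    regions.  With ``threshold=0`` bins partition by sign.  Runs wrap
    across the origin of circular chromosomes.
    """
    with np.errstate(invalid="ignore"):
        marginal = np.nanmean(diff.values, axis=1)
    regions: list[DifferentialRegion] = []
    for chrom in diff.bins["chrom"].unique():
        sel = np.flatnonzero((diff.bins["chrom"] == chrom).to_numpy())
        m = marginal[sel]
        starts = diff.bins["start"].to_numpy()[sel]
        ends = diff.bins["end"].to_numpy()[sel]
        if threshold > 0:
            state = np.where(m >= threshold, 1, np.where(m <= -threshold, -1, 0))
        else:
            state = np.where(m >= 0, 1, -1)
        state = np.where(np.isfinite(m), state, 0)
        n = state.size
        circular = diff.layout.is_circular(str(chrom)) if diff.layout is not None else False
        runs = _runs(state, circular)
        for sign, idx in runs:
            if sign == 0 or idx.size < min_run:
                continue
            regions.append(
                DifferentialRegion(
                    chrom=str(chrom),
                    start=int(starts[idx[0]]) + 1,
                    end=int(ends[idx[-1]]),
                    mean_log2=float(np.mean(m[idx])),
                    direction="up" if sign > 0 else "down",
                    n_bins=int(idx.size),
                )
            )
    return regions


def _runs(state: np.ndarray, circular: bool):
    """Maximal runs of equal state; on circular sequences the first and
    last runs merge when they share a state."""
    n = state.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(state)) + 1
    bounds = np.concatenate(([0], change, [n]))
    runs = [
        (int(state[bounds[k]]), np.arange(bounds[k], bounds[k + 1]))
        for k in range(len(bounds) - 1)
    ]
    if circular and len(runs) > 1 and runs[0][0] == runs[-1][0]:
        sign, first = runs[0]
        _, last = runs[-1]
        runs = runs[1:-1] + [(sign, np.concatenate((last, first)))]
    return runs


def region_pair_score(
    a: ContactMatrix,
    b: ContactMatrix,
    region_x: tuple[str, int, int],
    region_y: tuple[str, int, int],
    pseudocount: float | None = None,
) -> tuple[float, float, float]:
    """Mean contact probability of a region-by-region block in two maps.

    Regions are ``(chrom, start, end)`` in 1-based inclusive coordinates.
    Returns ``(mean_A, mean_B, log2((mean_B + pc) / (mean_A + pc)))`` with
    the differential-map pseudocount.
    """
    _require_same_bins(a, b)
    if pseudocount is None:
        pseudocount = 1.0 / (2.0 * min(a.depth, b.depth))

    def block(mat: ContactMatrix, region: tuple[str, int, int]) -> np.ndarray:
        chrom, start, end = region
        sel = (
            (mat.bins["chrom"] == chrom)
            & (mat.bins["end"] > start - 1)
            & (mat.bins["start"] < end)
        ).to_numpy()
        return np.flatnonzero(sel)

    ix = block(a, region_x)
    iy = block(a, region_y)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("empty region block")
    PA = a.dense()
    PB = b.dense()
    PA /= PA.sum()
    PB /= PB.sum()
    mean_a = float(PA[np.ix_(ix, iy)].mean())
    mean_b = float(PB[np.ix_(ix, iy)].mean())
    ratio = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
    return mean_a, mean_b, ratio
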