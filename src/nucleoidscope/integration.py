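"""Integration of contact structure with transcription, variants, and
sequence landmarks.

Covers MAPQ-filtered coverage binning, Savitzky-Golay smoothing, the
contact-signal / transcription Pearson correlation, a permutation test of
variant-contact enrichment, an ungapped sliding-window scan for the crtS
replication-licensing motif, and annotation of differential regions with
overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import pearsonr

from .contacts import ContactMatrix
from .structure import DifferentialRegion, Track, fire_score

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def bin_coverage(
    reads,
    mat_or_bins,
    mapq_min: int = 30,
    binsize: int | None = None,
) -> Track:
    """Per-bin coverage of reads with mapping quality strictly above a cutoff.

    ``reads`` is either a DataFrame with columns ``chrom, start, length,
    mapq`` (1-based start) or a per-base track ``{chrom: ndarray}`` (no
    MAPQ filter applies to a track).  A read spanning a bin boundary
    contributes its overlap to each bin.  Bins come from a contact matrix
    (to guarantee matched binning) or a bin table plus ``binsize``.
    """
    if isinstance(mat_or_bins, ContactMatrix):
        bins = mat_or_bins.bins
        binsize = mat_or_bins.binsize
    else:
        bins = mat_or_bins
        if binsize is None:
            raise ValueError("binsize required when bins are given directly")
    cov = np.zeros(len(bins))
    offsets = {c: int(np.flatnonzero((bins["chrom"] == c).to_numpy())[0]) for c in bins["chrom"].unique()}
    nb = {c: int(((bins["chrom"] == c).to_numpy()).sum()) for c in bins["chrom"].unique()}
    if isinstance(reads, dict):
        for chrom, track in reads.items():
            if chrom not in offsets:
                raise ValueError(f"track chromosome {chrom!r} not in bin table")
            track = np.asarray(track, dtype=float)
            edges = np.arange(0, track.size, binsize)
            sums = np.add.reduceat(track, edges)
            cov[offsets[chrom] : offsets[chrom] + sums.size] += sums[: nb[chrom]]
        return Track(bins=bins.copy(), values=cov, kind="coverage", binsize=binsize)
    kept = reads[reads["mapq"].to_numpy() > mapq_min]
    for chrom, start, length in kept[["chrom", "start", "length"]].itertuples(index=False):
        if chrom not in offsets:
            raise ValueError(f"read chromosome {chrom!r} not in bin table")
        g0 = int(start) - 1
        g1 = g0 + int(length)
        for b in range(g0 // binsize, (g1 - 1) // binsize + 1):
            lo, hi = max(g0, b * binsize), min(g1, (b + 1) * binsize)
            cov[offsets[chrom] + min(b, nb[chrom] - 1)] += hi - lo
    return Track(bins=bins.copy(), values=cov, kind="coverage", binsize=binsize)


def savgol_smooth(track: Track, window: int = 21, order: int = 3, circular: bool = True) -> Track:
    """Savitzky-Golay smoothing per chromosome.

    The filter fits a local polynomial of degree ``order`` in a centred
    odd window, so any polynomial signal of degree <= order passes
    through unchanged (away from the wrap seam when ``circular``).
    Circular chromosomes use wrap padding; with ``circular=False`` edge
    windows are fit with polynomial extrapolation instead.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    out = np.empty_like(track.values)
    for chrom in track.bins["chrom"].unique():
        sel = np.flatnonzero((track.bins["chrom"] == chrom).to_numpy())
        v = track.values[sel]
        if window > v.size:
            raise ValueError(f"window exceeds bin count of chromosome {chrom!r}")
        filled = np.nan_to_num(v)
        sm = savgol_filter(filled, window, order, mode="wrap" if circular else "interp")
        sm[~np.isfinite(v)] = np.nan
        out[sel] = sm
    return Track(bins=track.bins.copy(), values=out, kind=track.kind, binsize=track.binsize)


@dataclass
class CorrelationReport:
    """Pearson correlation of smoothed contact and transcription signals."""

    pearson_r: float
    per_chrom: dict[str, float]
    n_bins: int
    smoothing: tuple[int, int]
    signal_kind: str


def contact_transcription_correlation(
    mat: ContactMatrix,
    coverage: Track,
    signal_kind: str = "FIRE_Z",
    smoothing: tuple[int, int] = (21, 3),
    short_range_cap: int = 50_000,
) -> CorrelationReport:
    """Pearson r between a contact signal and binned transcription coverage.

    The contact signal is the FIRE-like z-score (default) or the sum of
    contacts within ``short_range_cap``; both tracks are Savitzky-Golay
    smoothed before correlating.  r is reported pooled over chromosomes
    and per chromosome, over unmasked finite bins.
    """
    if len(coverage.values) != mat.n_bins:
        raise ValueError("coverage track does not match matrix bins")
    if signal_kind == "FIRE_Z":
        signal = fire_score(mat, window=10_000)
    elif signal_kind == "short_range_sum":
        signal = fire_score(mat, window=short_range_cap)
        signal = Track(signal.bins, signal.values, "short_range_sum", signal.binsize)
    else:
        raise ValueError("signal_kind must be 'FIRE_Z' or 'short_range_sum'")
    window, order = smoothing
    sm_signal = savgol_smooth(signal, window, order)
    sm_cov = savgol_smooth(coverage, window, order)
    usable = np.isfinite(sm_signal.values) & np.isfinite(sm_cov.values)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable bins")
    pooled = float(pearsonr(sm_signal.values[usable], sm_cov.values[usable])[0])
    per_chrom: dict[str, float] = {}
    for chrom in mat.bins["chrom"].unique():
        sel = ((mat.bins["chrom"] == chrom).to_numpy()) & usable
        if sel.sum() >= 3:
            per_chrom[str(chrom)] = float(
                pearsonr(sm_signal.values[sel], sm_cov.values[sel])[0]
            )
    return CorrelationReport(
        pearson_r=pooled,
        per_chrom=per_chrom,
        n_bins=int(usable.sum()),
        smoothing=(window, order),
        signal_kind=signal_kind,
    )


@dataclass
class EnrichmentReport:
    """Permutation test of contact enrichment at variant-bearing bins."""

    observed_mean: float
    enrichment_ratio: float
    p_perm: float
    n_perm: int
    seed: int
    n_variant_bins: int
    null_means: np.ndarray = field(repr=False, default=None)


def variant_contact_enrichment(
    variants: pd.DataFrame,
    mat: ContactMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentReport:
    """Are variant-bearing bins more contact-rich than the rest of the genome?

    The statistic is the mean marginal contact count over unmasked bins
    containing at least one variant; the null redraws that many distinct
    bins uniformly (without replacement) from the unmasked bins.  The
    one-sided p-value uses the add-one estimator, so it is never below
    ``1 / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    marg = mat.marginals()
    mask = mat.mask if mat.mask is not None else np.zeros(mat.n_bins, bool)
    vbins = set()
    for chrom, pos in variants[["chrom", "pos"]].itertuples(index=False):
        try:
            b = mat.bin_index(str(chrom), int(pos))
        except KeyError:
            continue
        if not mask[b]:
            vbins.add(b)
    if not vbins:
        raise ValueError("no variant falls in an unmasked bin")
    vbins_arr = np.array(sorted(vbins))
    observed = float(marg[vbins_arr].mean())
    live = np.flatnonzero(~mask)
    k = vbins_arr.size
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, live.size))
    picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = marg[live[picks]].mean(axis=1)
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    ratio = observed / float(null.mean()) if null.mean() > 0 else np.inf
    return EnrichmentReport(
        observed_mean=observed,
        enrichment_ratio=ratio,
        p_perm=p,
        n_perm=n_perm,
        seed=seed,
        n_variant_bins=k,
        null_means=null,
    )


@dataclass
class CrtsHit:
    """Best ungapped match of the crtS motif on the first chromosome."""

    position: int  # 1-based start of the best window
    identity: float
    relative_replichore_position: float
    strand: str


def crts_scan(
    sequence: str,
    motif: str,
    ori1: int,
    ter1: int,
    circular: bool = True,
) -> CrtsHit:
    """Locate the crtS motif by best fraction-identity sliding window.

    Both strands are scanned (circularly when ``circular``); ambiguous
    bases simply count as mismatches.  The hit's position along the
    ori1->ter1 replichore arc that contains it is reported as a fraction
    in [0, 1] (a site two fifths of the way from ori to ter reports 0.4).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(motif) < 20:
        raise ValueError("motif must be at least 20 bp")
    seq = sequence.upper().encode()
    m = len(motif)
    L = len(seq)
    if m > L:
        raise ValueError("motif longer than sequence")
    padded = seq + (seq[: m - 1] if circular else b"")
    n_pos = L if circular else L - m + 1
    arr = np.frombuffer(padded, dtype=np.uint8)

    def identities(query: bytes) -> np.ndarray:
        q = np.frombuffer(query.upper().encode() if isinstance(query, str) else query, dtype=np.uint8)
        score = np.zeros(n_pos, dtype=np.int32)
        for k in range(m):
            score += arr[k : k + n_pos] == q[k]
        return score / m

    fwd = identities(motif)
    rev = identities(motif.upper().encode().translate(_COMPLEMENT)[::-1])
    if fwd.max() >= rev.max():
        pos0, ident, strand = int(np.argmax(fwd)), float(fwd.max()), "+"
    else:
        pos0, ident, strand = int(np.argmax(rev)), float(rev.max()), "-"
    arm = (ter1 - ori1) % L
    if arm == 0:
        raise ValueError("ori1 == ter1")
    t = (pos0 - ori1) % L
    if t <= arm:
        rel = t / arm
    else:
        rel = ((ori1 - pos0) % L) / (L - arm)
    return CrtsHit(
        position=pos0 + 1,
        identity=ident,
        relative_replichore_position=float(rel),
        strand=strand,
    )


def annotate_regions(
    regions: list[DifferentialRegion] | list[tuple[str, int, int]],
    genes: pd.DataFrame,
    deg_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Overlap differential regions with gene models and DEG status.

    ``genes`` needs ``gene_id, chrom, start, end`` (1-based inclusive); a
    gene overlaps a region when any bp overlaps.  ``deg_table`` (output of
    :func:`nucleoidscope.omics.call_degs` or any frame with ``gene_id``
    and ``direction``) contributes per-region up/down counts.
    """
    directions = {}
    if deg_table is not None:
        directions = dict(zip(deg_table["gene_id"], deg_table["direction"]))
    rows = []
    for region in regions:
        if isinstance(region, DifferentialRegion):
            chrom, start, end = region.chrom, region.start, region.end
            meta = region.direction
        else:
            chrom, start, end = region
            meta = ""
        hit = genes[
            (genes["chrom"] == chrom)
            & (genes["end"].astype(int) >= start)
            & (genes["start"].astype(int) <= end)
        ]
        gene_ids = list(hit["gene_id"])
        dirs = [directions.get(g, "none") for g in gene_ids]
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "region_direction": meta,
                "genes": gene_ids,
                "n_genes": len(gene_ids),
                "n_up": sum(d == "up" for d in dirs),
                "n_down": sum(d == "down" for d in dirs),
            }
        )
    return pd.DataFrame(rows)
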