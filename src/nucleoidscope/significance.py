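"""Distance-decay null model and significant-interaction calling.

The null model assigns every intra-chromosomal bin pair within a distance
window [L, U] to one of a set of equal-occupancy distance strata and
estimates the per-pair contact probability of each stratum from the data,
followed by isotonic (monotone non-increasing) smoothing along distance.
Significance of an observed pair is the upper-tail binomial probability
P(X >= observed) with n equal to the total contact count in the window
and per-pair success probability equal to the stratum probability times
the (normalized) product of the two bins' balancing biases.
Inter-chromosomal pairs, which carry no genomic distance, share a single
pooled expected probability.  Multiple testing is controlled by
Benjamini-Hochberg; a second pass removes pass-1-significant pairs,
refits the null and recomputes all p/q values, so that strong contacts do
not inflate their own expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .contacts import ContactMatrix


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DecayModel:
    """Equal-occupancy distance strata with smoothed contact probabilities."""

    strata: pd.DataFrame  # d_lo, d_hi, d_mean, n_pairs, prob
    total_pairs: int  # total contact count over modelled intra pairs
    L: int
    U: int
    n_strata: int
    inter_prob: float | None = None  # pooled per-pair probability, inter-chromosomal
    inter_total: int | None = None  # total inter-chromosomal contact count
    n_bins: int | None = None  # bin count of the matrix the model was fit on

    def prob_at(self, distances: np.ndarray) -> np.ndarray:
        """Smoothed per-pair probability for given genomic distances."""
        edges = self.strata["d_hi"].to_numpy()
        idx = np.searchsorted(edges, distances, side="left")
        idx = np.clip(idx, 0, len(edges) - 1)
        return self.strata["prob"].to_numpy()[idx]


def _intra_pairs(mat: ContactMatrix, L: int, U: int):
    """Unordered intra-chromosomal bin pairs with circular distance in [L, U].

    Pairs touching masked bins are excluded.  Returns global index arrays,
    distances, and observed pair counts.
    """
    if mat.layout is None:
        raise ValueError("matrix needs a layout to compute genomic distances")
    dense = mat.dense()
    mask = mat.mask if mat.mask is not None else np.zeros(mat.n_bins, bool)
    ii, jj, dd, cc = [], [], [], []
    for name in mat.layout.names:
        sl = mat.chrom_slice(name)
        d = mat.bin_distance_matrix(name)
        nloc = sl.stop - sl.start
        iu = np.triu_indices(nloc, k=1)
        dv = d[iu]
        keep = (dv >= L) & (dv <= U)
        gi = iu[0][keep] + sl.start
        gj = iu[1][keep] + sl.start
        live = ~(mask[gi] | mask[gj])
        gi, gj = gi[live], gj[live]
        ii.append(gi)
        jj.append(gj)
        dd.append(d[iu][keep][live])
        cc.append(dense[gi, gj])
    return (
        np.concatenate(ii),
        np.concatenate(jj),
        np.concatenate(dd),
        np.concatenate(cc),
    )


def _inter_pairs(mat: ContactMatrix):
    """Unordered inter-chromosomal bin pairs (unmasked) and their counts."""
    chrom = mat.bins["chrom"].to_numpy()
    mask = mat.mask if mat.mask is not None else np.zeros(mat.n_bins, bool)
    n = mat.n_bins
    iu = np.triu_indices(n, k=1)
    inter = chrom[iu[0]] != chrom[iu[1]]
    gi, gj = iu[0][inter], iu[1][inter]
    live = ~(mask[gi] | mask[gj])
    gi, gj = gi[live], gj[live]
    dense = mat.dense()
    return gi, gj, dense[gi, gj]


def fit_decay(
    mat: ContactMatrix,
    L: int = 20_000,
    U: int = 2_000_000,
    n_strata: int = 200,
    include_inter: bool = True,
    _exclude: set[tuple[int, int]] | None = None,
) -> DecayModel:
    """Fit the stratified distance-decay null model.

    Strata are built to hold approximately equal numbers of bin pairs
    (pairs at the same distance always share a stratum); each stratum's
    probability is its total contact count divided by the window total and
    by its pair count, then smoothed to be non-increasing in distance.
    ``_exclude`` drops specific pairs (used by the two-pass caller).
    """
    if U <= L:
        raise ValueError("U must exceed L")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    gi, gj, dist, counts = _intra_pairs(mat, L, U)
    if gi.size == 0:
        raise ValueError("no intra-chromosomal pairs in the distance window")
    # stratum boundaries always come from the full pair set so that a
    # two-pass refit re-estimates probabilities on identical strata
    uniq, inv = np.unique(dist, return_inverse=True)
    if _exclude:
        keep = np.array([(a, b) not in _exclude for a, b in zip(gi, gj)])
        gi, gj, counts, inv_kept = gi[keep], gj[keep], counts[keep], inv[keep]
    else:
        inv_kept = inv
    per_d_pairs = np.bincount(inv, minlength=uniq.size)
    per_d_counts = np.bincount(inv_kept, weights=counts, minlength=uniq.size)
    if uniq.size < n_strata:
        warnings.warn(
            f"only {uniq.size} distinct distances; reducing strata from {n_strata}",
            stacklevel=2,
        )
        n_strata_eff = uniq.size
    else:
        n_strata_eff = n_strata
    target = gi.size / n_strata_eff
    # greedy equal-occupancy grouping of consecutive distances
    stratum_of_d = np.empty(uniq.size, dtype=np.int64)
    acc = 0.0
    s = 0
    for k in range(uniq.size):
        if acc >= target and s < n_strata_eff - 1:
            s += 1
            acc = 0.0
        stratum_of_d[k] = s
        acc += per_d_pairs[k]
    n_s = s + 1
    pair_count = np.bincount(stratum_of_d, weights=per_d_pairs, minlength=n_s)
    contact_sum = np.bincount(stratum_of_d, weights=per_d_counts, minlength=n_s)
    d_mean = np.bincount(stratum_of_d, weights=per_d_pairs * uniq, minlength=n_s) / pair_count
    d_lo = np.array([uniq[stratum_of_d == k].min() for k in range(n_s)])
    d_hi = np.array([uniq[stratum_of_d == k].max() for k in range(n_s)])
    total = contact_sum.sum()
    if total == 0:
        raise ValueError("no contacts in the distance window")
    raw_prob = contact_sum / total / pair_count
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    prob = iso.fit_transform(d_mean, raw_prob, sample_weight=pair_count)
    norm = float(np.sum(prob * pair_count))
    if norm > 0:
        prob = prob / norm
    strata = pd.DataFrame(
        {"d_lo": d_lo, "d_hi": d_hi, "d_mean": d_mean, "n_pairs": pair_count, "prob": prob}
    )
    inter_prob = inter_total = None
    if include_inter:
        igi, igj, icounts = _inter_pairs(mat)
        if _exclude and igi.size:
            keep = np.array([(a, b) not in _exclude for a, b in zip(igi, igj)])
            igi, igj, icounts = igi[keep], igj[keep], icounts[keep]
        if igi.size:
            inter_total = int(icounts.sum())
            inter_prob = 1.0 / igi.size  # pooled: every inter pair shares the mean
    return DecayModel(
        strata=strata,
        total_pairs=int(total),
        L=L,
        U=U,
        n_strata=n_strata,
        inter_prob=inter_prob,
        inter_total=inter_total,
        n_bins=mat.n_bins,
    )


def _bias_products(mat: ContactMatrix, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    if mat.bias is None:
        return np.ones(gi.size)
    b = np.nan_to_num(mat.bias, nan=1.0)
    w = b[gi] * b[gj]
    mean = w.mean()
    return w / mean if mean > 0 else np.ones(gi.size)


def _score_pairs(mat: ContactMatrix, model: DecayModel):
    """p-values for all testable pairs under the decay model."""
    if model.n_bins is not None and model.n_bins != mat.n_bins:
        raise ValueError(
            f"decay model was fit on {model.n_bins} bins but the matrix has {mat.n_bins}"
        )
    gi, gj, dist, counts = _intra_pairs(mat, model.L, model.U)
    p_pair = model.prob_at(dist) * _bias_products(mat, gi, gj)
    p_pair = np.clip(p_pair, 1e-300, 1.0)
    pvals = stats.binom.sf(counts - 1, model.total_pairs, p_pair)
    frames = [
        pd.DataFrame(
            {
                "bin_i": gi,
                "bin_j": gj,
                "observed": counts,
                "expected_p": p_pair,
                "p_value": pvals,
                "kind": "intra",
            }
        )
    ]
    if model.inter_prob is not None and model.inter_total:
        igi, igj, icounts = _inter_pairs(mat)
        ip = np.clip(model.inter_prob * _bias_products(mat, igi, igj), 1e-300, 1.0)
        ipv = stats.binom.sf(icounts - 1, model.inter_total, ip)
        frames.append(
            pd.DataFrame(
                {
                    "bin_i": igi,
                    "bin_j": igj,
                    "observed": icounts,
                    "expected_p": ip,
                    "p_value": ipv,
                    "kind": "inter",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def call_significant(
    mat: ContactMatrix,
    model: DecayModel | None = None,
    passes: int = 2,
    p_thr: float = 0.01,
    q_thr: float = 0.01,
    min_count: int = 2,
    L: int = 20_000,
    U: int = 2_000_000,
    n_strata: int = 200,
) -> pd.DataFrame:
    """Call significant interactions against the distance-decay null.

    A pair is reported when p < ``p_thr``, q < ``q_thr`` and its observed
    count strictly exceeds ``min_count``.  With ``passes=2`` the null is
    refit after removing pass-1-significant pairs and all pairs are
    re-scored against the refined model.  Records are 1-based in the
    user-facing columns and sorted by q.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if model is None:
        model = fit_decay(mat, L=L, U=U, n_strata=n_strata)
    else:
        L, U, n_strata = model.L, model.U, model.n_strata
    scored = _score_pairs(mat, model)
    for _ in range(passes - 1):
        sig = scored[
            (scored["p_value"] < p_thr)
            & (scored["q_value"] < q_thr)
            & (scored["observed"] > min_count)
        ]
        if sig.empty:
            break
        exclude = set(zip(sig["bin_i"].astype(int), sig["bin_j"].astype(int)))
        model = fit_decay(mat, L=L, U=U, n_strata=n_strata, _exclude=exclude)
        scored = _score_pairs(mat, model)
    hits = scored[
        (scored["p_value"] < p_thr)
        & (scored["q_value"] < q_thr)
        & (scored["observed"] > min_count)
    ].copy()
    bins = mat.bins
    for side, col in (("bin_i", "1"), ("bin_j", "2")):
        idx = hits[side].to_numpy(dtype=int)
        hits[f"chrom{col}"] = bins["chrom"].to_numpy()[idx]
        hits[f"start{col}"] = bins["start"].to_numpy()[idx] + 1  # 1-based
    hits = hits.sort_values("q_value", ignore_index=True)
    return hits[
        [
            "chrom1",
            "start1",
            "chrom2",
            "start2",
            "bin_i",
            "bin_j",
            "observed",
            "expected_p",
            "p_value",
            "q_value",
            "kind",
        ]
    ]


def score_all_pairs(mat: ContactMatrix, model: DecayModel | None = None, **kwargs) -> pd.DataFrame:
    """p/q values for every testable pair (no thresholding); used for
    calibration checks."""
    if model is None:
        model = fit_decay(mat, **kwargs)
    return _score_pairs(mat, model)
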