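"""Synthetic Hi-C, transcription, and variant data with planted structure.

The generator emulates the structural phenomena of a two-chromosome
bacterial nucleoid so that every downstream operation can be verified
against planted ground truth:

* power-law distance decay of intra-chromosomal contacts (circular
  distance),
* chromosome interaction domains (CIDs) as within-domain contact
  enrichment between planted borders,
* an ori-ter secondary cross-diagonal from replichore alignment,
* a contact-depleted prophage region,
* a uniform inter-chromosomal background with an elevated ori2-crtS
  contact spot (plus a weaker symmetric ter1-ter2 companion spot),
* smooth multiplicative per-bin biases of the kind iterative correction
  removes,
* a transcription track positively coupled to local contact frequency,
* variants clustered inside the prophage region on a uniform background.

Contacts are drawn as a single multinomial over bin pairs so total depth
is controlled exactly, matching valid-pairs bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactMatrix, make_bins
from .layout import GenomeLayout, default_layout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Irregularly spaced default CID borders (fractions of chromosome length);
# segments are all wider than the 100 kb DI window at the default sizes.
_DEFAULT_BORDER_FRACS = (0.06, 0.22, 0.46, 0.68, 0.86)


@dataclass
class ContactModelParams:
    """Parameters of the planted contact model.

    ``alpha`` is the distance-decay exponent applied to the circular
    bin-level distance; ``beta_cid`` multiplies within-CID cells;
    ``gamma_arm`` multiplies cells on the ori-ter cross-diagonal;
    ``delta_prophage`` multiplies intra-chromosomal cells with an endpoint
    in a prophage region; ``epsilon_trans`` is the uniform
    inter-chromosomal background weight and ``rho_ori2crts`` the
    multiplier of the ori2-crtS spot (its ter1-ter2 companion gets half
    the excess).  ``bias_amplitude`` is the standard deviation of the
    smooth log-bias field.
    """

    alpha: float = 1.0
    beta_cid: float = 2.0
    gamma_arm: float = 1.5
    delta_prophage: float = 0.5
    epsilon_trans: float = 0.005
    rho_ori2crts: float = 8.0
    n_pairs: int = 2_000_000
    bias_amplitude: float = 0.3
    cid_borders: dict[str, list[int]] | None = None
    spot_extent_bins: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("beta_cid", "gamma_arm", "delta_prophage", "epsilon_trans", "rho_ori2crts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.delta_prophage <= 1:
            raise ValueError("delta_prophage must be in (0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.cid_borders is not None:
            for chrom, borders in self.cid_borders.items():
                if list(borders) != sorted(borders) or len(set(borders)) != len(borders):
                    raise ValueError(f"cid_borders for {chrom!r} must be strictly increasing")


def wt_params(**overrides) -> ContactModelParams:
    """Wild-type-like defaults: no prophage depletion."""
    return ContactModelParams(delta_prophage=1.0, **overrides)


def mutant_params(**overrides) -> ContactModelParams:
    """Slower-growth-mutant-like defaults: depleted prophage region and a
    weakened ori2-crtS contact."""
    overrides.setdefault("delta_prophage", 0.5)
    overrides.setdefault("rho_ori2crts", 4.0)
    return ContactModelParams(**overrides)


def default_cid_borders(layout: GenomeLayout, grid: int = 10_000) -> dict[str, list[int]]:
    """Five irregularly spaced borders per chromosome, snapped to ``grid``."""
    out: dict[str, list[int]] = {}
    for name, length, _ in layout.chroms:
        out[name] = [int(round(f * length / grid)) * grid for f in _DEFAULT_BORDER_FRACS]
    return out


def _cid_ids(starts: np.ndarray, borders: list[int], length: int) -> np.ndarray:
    """Domain id per bin on a circular chromosome partitioned by borders.

    The segment between the last and first border wraps around the origin
    and forms a single domain.
    """
    if not borders:
        return np.zeros(starts.size, dtype=np.int64)
    edges = np.asarray(sorted(borders))
    ids = np.searchsorted(edges, starts, side="right")
    ids[ids == len(edges)] = 0  # wrap segment joins the pre-first-border one
    return ids


def expected_weight_matrix(
    layout: GenomeLayout, params: ContactModelParams, binsize: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Dense matrix of expected (unnormalized) contact weights per bin pair."""
    bins = make_bins(layout, binsize)
    for name, length, _ in layout.chroms:
        if length // binsize < 10:
            raise ValueError(f"binsize leaves fewer than 10 bins on {name!r}")
    n = len(bins)
    W = np.zeros((n, n))
    chrom_arr = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    borders = params.cid_borders or default_cid_borders(layout)
    prophage = np.zeros(n, dtype=bool)
    for chrom, s, e in layout.prophage_regions:
        prophage |= (chrom_arr == chrom) & (starts >= s) & (starts < e)
    for name, length, circular in layout.chroms:
        sel = np.flatnonzero(chrom_arr == name)
        st = starts[sel]
        d = np.abs(st[:, None] - st[None, :]).astype(float)
        if circular:
            d = np.minimum(d, length - d)
        w = np.power(1.0 + d / binsize, -params.alpha)
        ids = _cid_ids(st, borders.get(name, []), length)
        w = np.where(ids[:, None] == ids[None, :], params.beta_cid * w, w)
        # ori-ter cross-diagonal: bins symmetric about the ori/ter axis
        ori = layout.ori.get(name, 0)
        x = (st - ori) % length
        ssum = (x[:, None] + x[None, :]) % length
        arm = np.minimum(ssum, length - ssum) <= binsize
        w = np.where(arm, params.gamma_arm * w, w)
        pro = prophage[sel]
        w = np.where(pro[:, None] | pro[None, :], params.delta_prophage * w, w)
        W[np.ix_(sel, sel)] = w
    # inter-chromosomal background and spots
    names = layout.names
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa = np.flatnonzero(chrom_arr == names[a])
            sb = np.flatnonzero(chrom_arr == names[b])
            W[np.ix_(sa, sb)] = params.epsilon_trans
            W[np.ix_(sb, sa)] = params.epsilon_trans
    if len(names) >= 2 and layout.crts is not None:
        first, second = names[0], names[1]

        def _spot(chrom_a: str, pos_a: int, chrom_b: str, pos_b: int, mult: float) -> None:
            # tethering zones span tens of kb, so the multiplier covers a
            # small neighbourhood around the central bin pair (wrapping)
            half = params.spot_extent_bins
            sel_a = np.flatnonzero(chrom_arr == chrom_a)
            sel_b = np.flatnonzero(chrom_arr == chrom_b)
            ca = min(pos_a // binsize, sel_a.size - 1)
            cb = min(pos_b // binsize, sel_b.size - 1)
            ia = sel_a[(ca + np.arange(-half, half + 1)) % sel_a.size]
            ib = sel_b[(cb + np.arange(-half, half + 1)) % sel_b.size]
            W[np.ix_(ia, ib)] *= mult
            W[np.ix_(ib, ia)] = W[np.ix_(ia, ib)].T

        _spot(first, layout.crts[1], second, layout.ori.get(second, 0), params.rho_ori2crts)
        if first in layout.ter and second in layout.ter:
            companion = 1.0 + (params.rho_ori2crts - 1.0) / 2.0
            _spot(first, layout.ter[first], second, layout.ter[second], companion)
    return bins, W


def _smooth_bias(n: int, amplitude: float, rng: np.random.Generator, window: int = 11) -> np.ndarray:
    """Smooth positive multiplicative bias vector with mean 1.

    Exponential of a moving-average of white noise (a cheap smooth
    Gaussian-field proxy), scaled so the log-bias standard deviation is
    ``amplitude`` and mean-normalized to 1.
    """
    if amplitude == 0:
        return np.ones(n)
    z = rng.standard_normal(n + window - 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(z, kernel, mode="valid")
    sd = smooth.std()
    if sd == 0:
        return np.ones(n)
    b = np.exp(amplitude * smooth / sd)
    return b / b.mean()


def simulate_contact_map(
    layout: GenomeLayout,
    params: ContactModelParams,
    binsize: int = 10_000,
) -> tuple[ContactMatrix, ContactMatrix, np.ndarray]:
    """Draw (true, observed, bias) matrices from the planted contact model.

    Expected weights are normalized to probabilities over unordered bin
    pairs and ``n_pairs`` contacts are drawn as one multinomial.  The
    *true* matrix keeps those counts; the *observed* matrix multiplies them
    by the rank-1 bias ``b_i * b_j`` and re-rounds.
    """
    min_len = min(length for _, length, _ in layout.chroms)
    if binsize > min_len:
        raise ValueError("binsize larger than the smallest chromosome")
    rng = np.random.default_rng(params.seed)
    bins, W = expected_weight_matrix(layout, params, binsize)
    n = len(bins)
    iu = np.triu_indices(n)
    weights = W[iu].astype(float)
    p = weights / weights.sum()
    draws = rng.multinomial(params.n_pairs, p)
    M = np.zeros((n, n))
    M[iu] = draws
    M = M + M.T  # doubles the diagonal, per the matrix convention
    true = ContactMatrix(bins=bins.copy(), counts=sp.csr_matrix(M), binsize=binsize, layout=layout)
    bias = _smooth_bias(n, params.bias_amplitude, rng)
    observed_dense = np.rint(M * np.outer(bias, bias))
    observed = ContactMatrix(
        bins=bins.copy(), counts=sp.csr_matrix(observed_dense), binsize=binsize, layout=layout
    )
    return true, observed, bias


def simulate_pairs(
    layout: GenomeLayout,
    params: ContactModelParams,
    binsize: int = 10_000,
) -> pd.DataFrame:
    """Draw a valid-pairs table (7 columns) from the planted contact model.

    Bin pairs are drawn as in :func:`simulate_contact_map` and each contact
    gets uniform positions inside its two bins; binning the result at
    ``binsize`` reproduces the drawn matrix exactly.
    """
    rng = np.random.default_rng(params.seed)
    bins, W = expected_weight_matrix(layout, params, binsize)
    n = len(bins)
    iu = np.triu_indices(n)
    weights = W[iu].astype(float)
    draws = rng.multinomial(params.n_pairs, weights / weights.sum())
    bi = np.repeat(iu[0], draws)
    bj = np.repeat(iu[1], draws)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()

    def positions(b: np.ndarray) -> np.ndarray:
        span = ends[b] - starts[b]
        return starts[b] + rng.integers(0, span) + 1  # 1-based

    pos1 = positions(bi)
    pos2 = positions(bj)
    strands = np.array(["+", "-"])
    df = pd.DataFrame(
        {
            "read_id": np.char.add("r", np.arange(bi.size).astype(str)),
            "chrom1": chroms[bi],
            "pos1": pos1,
            "strand1": strands[rng.integers(0, 2, bi.size)],
            "chrom2": chroms[bj],
            "pos2": pos2,
            "strand2": strands[rng.integers(0, 2, bi.size)],
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)


@dataclass
class CouplingParams:
    """Transcription model: log-normal baseline expression coupled to the
    local-interaction (FIRE) z-score of the gene's bin."""

    k_fire: float = 1.0
    gene_count: int = 4600
    baseline_mu: float = 0.0
    baseline_sigma: float = 1.0
    libsize: int = 1_000_000
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_fire):
            raise ValueError("k_fire must be finite")
        if self.gene_count < 1:
            raise ValueError("gene_count must be >= 1")
        if self.libsize < 1:
            raise ValueError("libsize must be >= 1")
        if self.baseline_sigma < 0:
            raise ValueError("baseline_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _place_genes(
    layout: GenomeLayout, n_genes: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Genes placed uniformly (by length) with log-normal lengths ~ 0.9 kb."""
    lengths = np.array([layout.length(c) for c in layout.names], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=lengths / lengths.sum())
    gene_len = np.clip(
        np.exp(rng.normal(np.log(900.0), 0.4, size=n_genes)), 150, 6000
    ).astype(np.int64)
    starts = np.empty(n_genes, dtype=np.int64)
    for i, L in enumerate(lengths.astype(np.int64)):
        m = chrom_idx == i
        starts[m] = rng.integers(0, np.maximum(L - gene_len[m], 1))
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": np.array(layout.names)[chrom_idx],
            "start": starts + 1,  # 1-based inclusive
            "end": starts + gene_len,
            "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
            "length": gene_len,
        }
    )
    return df.sort_values(["chrom", "start"], ignore_index=True)


def _footprint_coverage(
    genes: pd.DataFrame, values: np.ndarray, bins: pd.DataFrame, binsize: int
) -> np.ndarray:
    """Spread a per-gene total over the bins its footprint overlaps."""
    cov = np.zeros(len(bins))
    offsets = {c: int(np.flatnonzero((bins["chrom"] == c).to_numpy())[0]) for c in bins["chrom"].unique()}
    nb = {c: int(((bins["chrom"] == c).to_numpy()).sum()) for c in bins["chrom"].unique()}
    for (chrom, start, end), val in zip(
        genes[["chrom", "start", "end"]].itertuples(index=False), values
    ):
        if val == 0:
            continue
        g0, g1 = start - 1, end  # 0-based half-open
        b0, b1 = g0 // binsize, (g1 - 1) // binsize
        glen = g1 - g0
        for b in range(b0, b1 + 1):
            lo = max(g0, b * binsize)
            hi = min(g1, (b + 1) * binsize)
            cov[offsets[chrom] + min(b, nb[chrom] - 1)] += val * (hi - lo) / glen
    return cov


def simulate_transcription(
    layout: GenomeLayout,
    fire_track: np.ndarray,
    coupling: CouplingParams,
    binsize: int = 10_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene counts coupled to a per-bin FIRE-like z-score track.

    Expected expression of gene *g* is
    ``exp(N(mu, sigma)) * exp(k_fire * z(bin of g))``; replicate counts are
    Poisson draws scaled so each replicate totals ~``libsize`` fragments.
    Returns the gene table (one ``count_rep{r}`` column per replicate) and
    the per-bin coverage track of pooled counts spread over gene
    footprints.
    """
    if not np.all(np.isfinite(np.nan_to_num(fire_track))):
        raise ValueError("fire_track must be finite")
    rng = np.random.default_rng(coupling.seed)
    bins = make_bins(layout, binsize)
    if len(fire_track) != len(bins):
        raise ValueError("fire_track length does not match bin count")
    genes = _place_genes(layout, coupling.gene_count, rng)
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) // 2
    offsets = {c: int(np.flatnonzero((bins["chrom"] == c).to_numpy())[0]) for c in layout.names}
    nb = {c: int(((bins["chrom"] == c).to_numpy()).sum()) for c in layout.names}
    bin_of = np.array(
        [
            offsets[c] + min((m - 1) // binsize, nb[c] - 1)
            for c, m in zip(genes["chrom"], mid)
        ]
    )
    z = np.nan_to_num(np.asarray(fire_track, dtype=float)[bin_of])
    base = np.exp(rng.normal(coupling.baseline_mu, coupling.baseline_sigma, size=len(genes)))
    expected = base * np.exp(coupling.k_fire * z)
    lam = coupling.libsize * expected / expected.sum()
    genes["expected_expression"] = expected
    counts = np.zeros(len(genes), dtype=np.int64)
    for r in range(coupling.n_replicates):
        c = rng.poisson(lam)
        genes[f"count_rep{r + 1}"] = c
        counts += c
    coverage = _footprint_coverage(genes, counts, bins, binsize)
    return genes, coverage


def simulate_expression_pair(
    layout: GenomeLayout,
    coupling: CouplingParams,
    fold_changes: np.ndarray | None = None,
    binsize: int = 10_000,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two-condition gene counts sharing one baseline expression structure.

    ``fold_changes`` multiplies condition-B expected expression per gene
    (default all ones, the null).  Replicate noise is independent between
    conditions; the gene table, condition-A counts and condition-B counts
    (genes x replicates) are returned.
    """
    rng = np.random.default_rng(coupling.seed)
    genes = _place_genes(layout, coupling.gene_count, rng)
    base = np.exp(rng.normal(coupling.baseline_mu, coupling.baseline_sigma, size=len(genes)))
    if fold_changes is None:
        fold_changes = np.ones(len(genes))
    fold_changes = np.asarray(fold_changes, dtype=float)
    if fold_changes.shape != (len(genes),):
        raise ValueError("fold_changes must have one entry per gene")
    lam_a = coupling.libsize * base / base.sum()
    expected_b = base * fold_changes
    lam_b = coupling.libsize * expected_b / expected_b.sum()
    counts_a = rng.poisson(lam_a[:, None], size=(len(genes), coupling.n_replicates))
    counts_b = rng.poisson(lam_b[:, None], size=(len(genes), coupling.n_replicates))
    genes["true_fold_change"] = fold_changes
    return genes, counts_a, counts_b


def simulate_variants(
    layout: GenomeLayout,
    n_background: int,
    cluster: tuple[tuple[str, int, int], int] | None = None,
    seed: int = 0,
    snv_fraction: float = 0.8,
) -> pd.DataFrame:
    """Uniform background variants plus a positional cluster.

    ``cluster`` is ``((chrom, start, end), n_cluster)`` with a half-open
    bp region.  Rows are typed SNV / insertion / deletion with concrete
    ref/alt allele strings (VCF style, no dash alleles).
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    positions: list[int] = []
    lengths = np.array([layout.length(c) for c in layout.names], dtype=float)
    if n_background:
        ci = rng.choice(len(lengths), size=n_background, p=lengths / lengths.sum())
        for i in ci:
            chroms.append(layout.names[i])
            positions.append(int(rng.integers(1, lengths[i] + 1)))
    if cluster is not None:
        (chrom, start, end), n_cluster = cluster
        if n_cluster < 0:
            raise ValueError("n_cluster must be >= 0")
        if chrom not in layout.names or not (0 <= start < end <= layout.length(chrom)):
            raise ValueError("cluster region outside chromosome bounds")
        for _ in range(n_cluster):
            chroms.append(chrom)
            positions.append(int(rng.integers(start + 1, end + 1)))  # 1-based
    rows = []
    for chrom, pos in zip(chroms, positions):
        ref = chr(_BASES[rng.integers(0, 4)])
        if rng.random() < snv_fraction:
            alt = ref
            while alt == ref:
                alt = chr(_BASES[rng.integers(0, 4)])
            var_type = "SNV"
        else:
            indel = "".join(chr(_BASES[i]) for i in rng.integers(0, 4, size=rng.integers(1, 4)))
            if rng.random() < 0.5:
                alt, var_type = ref + indel, "insertion"
            else:
                ref, alt, var_type = ref + indel, ref, "deletion"
        rows.append((chrom, pos, ref, alt, var_type))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "var_type"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def random_sequence(length: int, seed: int = 0, gc: float = 0.45) -> str:
    """Random DNA sequence with the given GC fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
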