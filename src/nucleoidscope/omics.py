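"""Expression quantification, DEG thresholding, and variant clustering.

Differential expression uses the field-standard FPKM unit and the
fold-change >= 2, FDR < 0.05 rule.  With only two replicates per
condition a dispersion estimate is not meaningful, so the p-value comes
from a two-sided exact binomial test of a gene's pooled counts against
the library-size ratio; Benjamini-Hochberg controls the FDR.  Variant
tables (resequencing calls) are parsed into typed records and clustered
positionally by single-linkage gap chaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .significance import bh_fdr

_DASHES = {"-", "–", "−", "—", ""}


def fpkm(count, gene_length, libsize):
    """Fragments per kilobase of transcript per million mapped fragments.

    ``1e9 * count / (libsize * gene_length)``; vectorized over any input.
    """
    count = np.asarray(count, dtype=float)
    gene_length = np.asarray(gene_length, dtype=float)
    libsize = np.asarray(libsize, dtype=float)
    if np.any(gene_length <= 0):
        raise ValueError("gene_length must be >= 1")
    if np.any(libsize <= 0):
        raise ValueError("libsize must be >= 1")
    out = 1e9 * count / (libsize * gene_length)
    return float(out) if out.ndim == 0 else out


def call_degs(
    genes: pd.DataFrame,
    counts_a,
    counts_b,
    fc_thr: float = 2.0,
    fdr_thr: float = 0.05,
    libsize_a=None,
    libsize_b=None,
    pseudo_fpkm: float = 0.1,
) -> pd.DataFrame:
    """Differential-expression calls between two conditions.

    ``genes`` needs ``gene_id`` and ``length`` columns; ``counts_a`` /
    ``counts_b`` are genes-by-replicates count arrays.  Per-replicate
    library sizes default to column sums.  Fold change is the ratio of
    mean FPKM (B over A) after adding ``pseudo_fpkm`` to both means; the
    p-value is a two-sided exact binomial test of pooled counts against
    the pooled library-size ratio.  A gene is a DEG when fold change is
    >= ``fc_thr`` or <= 1/``fc_thr`` AND q < ``fdr_thr``.  All-zero genes
    are skipped (flagged, never called).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    ng = len(genes)
    if counts_a.shape[0] != ng or counts_b.shape[0] != ng:
        raise ValueError("count arrays must have one row per gene")
    if libsize_a is None:
        libsize_a = counts_a.sum(axis=0)
    if libsize_b is None:
        libsize_b = counts_b.sum(axis=0)
    libsize_a = np.asarray(libsize_a, dtype=float)
    libsize_b = np.asarray(libsize_b, dtype=float)
    length = genes["length"].to_numpy(dtype=float)
    fpkm_a = 1e9 * counts_a / (libsize_a[None, :] * length[:, None])
    fpkm_b = 1e9 * counts_b / (libsize_b[None, :] * length[:, None])
    mean_a = fpkm_a.mean(axis=1)
    mean_b = fpkm_b.mean(axis=1)
    fold = (mean_b + pseudo_fpkm) / (mean_a + pseudo_fpkm)
    pooled_a = counts_a.sum(axis=1)
    pooled_b = counts_b.sum(axis=1)
    total = pooled_a + pooled_b
    skipped = total == 0
    ratio_b = libsize_b.sum() / (libsize_a.sum() + libsize_b.sum())
    pvals = np.ones(ng)
    for i in np.flatnonzero(~skipped):
        pvals[i] = stats.binomtest(int(pooled_b[i]), int(total[i]), ratio_b).pvalue
    qvals = np.full(ng, np.nan)
    live = ~skipped
    qvals[live] = bh_fdr(pvals[live])
    passes_fc = (fold >= fc_thr) | (fold <= 1.0 / fc_thr)
    deg = live & passes_fc & (qvals < fdr_thr)
    out = genes.copy()
    out["mean_fpkm_a"] = mean_a
    out["mean_fpkm_b"] = mean_b
    out["fold_change"] = fold
    out["log2_fold_change"] = np.log2(fold)
    out["p_value"] = np.where(live, pvals, np.nan)
    out["q_value"] = qvals
    out["skipped"] = skipped
    out["deg"] = deg
    out["direction"] = np.where(deg, np.where(fold > 1, "up", "down"), "none")
    return out


@dataclass
class VariantCluster:
    """Positional cluster of variants on one chromosome."""

    chrom: str
    start: int  # 1-based
    end: int
    n_variants: int
    members: list[int]  # row indices into the variant table, sorted


def _norm_allele(x) -> str:
    s = "" if x is None or (isinstance(x, float) and np.isnan(x)) else str(x).strip()
    return "" if s in _DASHES else s


def parse_variant_table(source) -> pd.DataFrame:
    """Parse a resequencing variant table (TSV path, file, or DataFrame).

    Expected columns: ``chrom, pos, ref, alt, effect, product`` and
    optionally ``differential_expression``.  Dash alleles (pure
    insertions/deletions written with a "-" placeholder) are normalized to
    empty strings; ``var_type`` is inferred from the allele lengths and
    ``frame_effect`` from the effect/product annotations (rows annotated
    only as upstream/downstream of an ORF get ``upstream``/``other`` and
    are excluded from frameshift accounting).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        ref = _norm_allele(d["ref"])
        alt = _norm_allele(d["alt"])
        try:
            pos = int(d["pos"])
        except (TypeError, ValueError):
            raise ValueError(f"row {row_no}: unparseable position {d['pos']!r}") from None
        if pos < 1:
            raise ValueError(f"row {row_no}: position must be >= 1")
        if ref == "" and alt == "":
            raise ValueError(f"row {row_no}: both alleles empty")
        if len(ref) == 1 and len(alt) == 1:
            if ref == alt:
                raise ValueError(f"row {row_no}: SNV with identical ref and alt")
            var_type = "SNV"
        elif len(alt) > len(ref):
            var_type = "insertion"
        elif len(alt) < len(ref):
            var_type = "deletion"
        else:
            if ref == alt:
                raise ValueError(f"row {row_no}: variant with identical alleles")
            var_type = "substitution"
        effect = str(d.get("effect", "") or "").strip()
        product = str(d.get("product", "") or "").strip()
        low = effect.lower()
        if product.lower().startswith("upstream"):
            frame_effect = "upstream"
        elif "non-frameshift" in low:
            frame_effect = "non-frameshift"
        elif "frameshift" in low:
            frame_effect = "frameshift"
        else:
            frame_effect = "other"
        net = len(alt) - len(ref)
        records.append(
            {
                "chrom": str(d["chrom"]).strip(),
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "var_type": var_type,
                "net_length_change": net,
                "frame_effect": frame_effect,
                "effect": effect,
                "product": product,
                "expression_note": str(d.get("differential_expression", "") or "").strip(),
            }
        )
    return pd.DataFrame.from_records(records)


def variant_cluster_scan(variants: pd.DataFrame, max_gap: int = 5000) -> list[VariantCluster]:
    """Single-linkage positional clustering of variants.

    Consecutive same-chromosome variants whose positions differ by at most
    ``max_gap`` bp join one cluster; cluster spans run from the smallest
    to the largest member position.  Clusters are returned sorted by
    member count (descending), then position.  Every variant belongs to
    exactly one cluster.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if "pos" not in variants.columns or "chrom" not in variants.columns:
        raise ValueError("variant table needs chrom and pos columns")
    order = variants.sort_values(["chrom", "pos"], kind="mergesort")
    clusters: list[VariantCluster] = []
    cur_rows: list[int] = []
    cur_chrom = None
    last_pos = None

    def flush():
        if cur_rows:
            pos = variants["pos"].to_numpy()[cur_rows]
            clusters.append(
                VariantCluster(
                    chrom=str(cur_chrom),
                    start=int(pos.min()),
                    end=int(pos.max()),
                    n_variants=len(cur_rows),
                    members=sorted(cur_rows),
                )
            )

    for idx, chrom, pos in zip(order.index, order["chrom"], order["pos"]):
        if cur_chrom != chrom or (last_pos is not None and pos - last_pos > max_gap):
            flush()
            cur_rows = []
            cur_chrom = chrom
        cur_rows.append(int(idx))
        last_pos = pos
    flush()
    clusters.sort(key=lambda c: (-c.n_variants, c.chrom, c.start))
    return clusters


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("nucleoidscope.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_mutant_indels() -> pd.DataFrame:
    """Bundled indel calls for the V. natriegens slower-growth mutant
    (vs its wild type), parsed into typed variant records."""
    return parse_variant_table(_load_table("mutant_indels.tsv"))


def load_mutant_snps() -> pd.DataFrame:
    """Bundled single-nucleotide variant calls (the reported subset outside
    the main variant hotspot) for the slower-growth mutant."""
    return parse_variant_table(_load_table("mutant_snps_selected.tsv"))


def load_region_genes(which: str) -> pd.DataFrame:
    """Bundled gene annotations of the differential-contact regions.

    ``which`` is ``"chr1"`` (prophage-associated region of chromosome 1)
    or ``"chr2"`` (anaerobic-metabolism region of chromosome 2).
    """
    name = {"chr1": "chr1_region_genes.tsv", "chr2": "chr2_region_genes.tsv"}[which]
    df = _load_table(name)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df
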