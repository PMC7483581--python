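"""Readers and writers for the plain-text interchange formats.

Pairs are 7-column TSV (readID, chrom1, pos1, strand1, chrom2, pos2,
strand2); matrices travel as a bins BED (0-based half-open) plus a COO
triplet TSV of upper-triangle pair counts; 1D tracks as bedGraph;
variants as minimal VCF 4.2; gene models as GFF3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import PAIRS_COLUMNS, ContactMatrix
from .layout import GenomeLayout
from .structure import Track


def read_pairs(path) -> pd.DataFrame:
    """Read a 7-column valid-pairs TSV (gzip transparent, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=PAIRS_COLUMNS)
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[PAIRS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_matrix(mat: ContactMatrix, bins_path, coo_path) -> None:
    """Write bins as BED and the upper triangle as COO pair counts.

    The diagonal is stored as intra-bin pair counts (half the internal
    doubled-diagonal value).
    """
    bed = mat.bins.copy()
    bed.to_csv(bins_path, sep="\t", header=False, index=False)
    dense = mat.dense()
    iu = np.triu_indices(mat.n_bins)
    vals = dense[iu].astype(float)
    diag = iu[0] == iu[1]
    vals[diag] = vals[diag] / 2.0
    nz = vals != 0
    pd.DataFrame({"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]}).to_csv(
        coo_path, sep="\t", header=False, index=False
    )


def read_matrix(bins_path, coo_path, layout: GenomeLayout | None = None) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t", header=None, names=["chrom", "start", "end"])
    binsize = int((bins["end"] - bins["start"]).max())
    coo = pd.read_csv(coo_path, sep="\t", header=None, names=["bin1", "bin2", "count"])
    n = len(bins)
    M = np.zeros((n, n))
    i = coo["bin1"].to_numpy(dtype=int)
    j = coo["bin2"].to_numpy(dtype=int)
    v = coo["count"].to_numpy(dtype=float)
    M[i, j] = v
    M[j, i] = v
    diag = np.arange(n)
    M[diag, diag] = M[diag, diag] * 2.0
    return ContactMatrix(bins=bins, counts=sp.csr_matrix(M), binsize=binsize, layout=layout)


def write_bedgraph(track: Track, path) -> None:
    df = track.bins[["chrom", "start", "end"]].copy()
    df["value"] = track.values
    df = df[np.isfinite(df["value"])]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, bins: pd.DataFrame, binsize: int, kind: str = "coverage") -> Track:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    key = dict(zip(zip(df["chrom"], df["start"]), df["value"]))
    values = np.array(
        [key.get((c, s), np.nan) for c, s in zip(bins["chrom"], bins["start"])]
    )
    return Track(bins=bins.copy(), values=values, kind=kind, binsize=binsize)


def write_vcf(variants: pd.DataFrame, path, layout: GenomeLayout | None = None) -> None:
    """Write variants (chrom, pos, ref, alt columns) as minimal VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nucleoidscope\n")
        if layout is not None:
            for name, length, _ in layout.chroms:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k, row in enumerate(variants.itertuples(index=False)):
            d = row._asdict()
            ref = d["ref"] or "N"
            alt = d["alt"] or "N"
            info = f"TYPE={d.get('var_type', '.')}" if d.get("var_type") else "."
            fh.write(f"{d['chrom']}\t{d['pos']}\tv{k}\t{ref}\t{alt}\t.\t.\t{info}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a (plain-text) VCF into a chrom/pos/ref/alt frame via pysam."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else ""
            rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt})
    return pd.DataFrame(rows)


def write_gff3(genes: pd.DataFrame, path, source: str = "nucleoidscope") -> None:
    """Write a gene table (gene_id, chrom, start, end, strand) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            d = row._asdict()
            strand = d.get("strand", "+") or "+"
            fh.write(
                f"{d['chrom']}\t{source}\tgene\t{d['start']}\t{d['end']}\t.\t{strand}\t.\t"
                f"ID={d['gene_id']};Name={d['gene_id']}\n"
            )


def read_gff3(path, featuretype: str = "gene") -> pd.DataFrame:
    """Read gene models from GFF3 into a gene table."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # malformed rows surface with context
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    rows = []
    for feat in db.features_of_type(featuretype):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")
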