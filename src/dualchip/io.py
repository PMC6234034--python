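"""Readers and writers for the standard formats at the pipeline boundary.

FASTA via Biopython, GFF3 via gffutils, SAM via pysam, plus 6-column BED for
aligned fragments (name column = library key ``condition:target:replicate``),
bedGraph coverage, and TSV tables.  External formats use their native
conventions (GFF3 1-based closed, SAM 1-based); everything in memory is
0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    AlignedRead,
    Contig,
    FusedGenome,
    Gene,
    GenomicInterval,
    READ_COLUMNS,
    as_read_frame,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_contigs(path: str | os.PathLike, organism: str) -> list[Contig]:
    """Contig names and lengths from a FASTA file; sequence content is not kept."""
    return [Contig(rec.id, len(rec.seq), organism) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fused_genome(
    fasta_path: str | os.PathLike,
    table_path: str | os.PathLike,
    genome: FusedGenome,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write the fused reference: FASTA (if sequences given) + contig table TSV."""
    if sequences is not None:
        write_fasta(fasta_path, {c.name: sequences[c.name] for c in genome.contigs})
    genome.contig_table().to_csv(table_path, sep="\t", index=False)


def read_contig_table(path: str | os.PathLike) -> FusedGenome:
    df = pd.read_csv(path, sep="\t")
    contigs = [Contig(str(r.name), int(r.length), str(r.organism))
               for r in df.itertuples(index=False)]
    return FusedGenome(contigs)


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------


def read_gff3_genes(
    path: str | os.PathLike,
    tf_attribute: str = "is_tf",
    cluster_attribute: str = "cluster_id",
    feature_type: str = "gene",
) -> list[Gene]:
    """Parse gene models from GFF3 (1-based closed -> 0-based half-open).

    The attribute keys carrying the transcription-factor flag and the
    secondary-metabolism cluster membership are configurable to match
    whatever the annotation provides.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        attrs = dict(feat.attributes)
        tf = attrs.get(tf_attribute, ["false"])[0].lower() in ("1", "true", "yes")
        cluster = attrs.get(cluster_attribute, [None])[0]
        gene_id = attrs.get("ID", [feat.id])[0]
        genes.append(
            Gene(
                id=gene_id,
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                is_tf=tf,
                cluster_id=cluster,
            )
        )
    return genes


def write_gff3_genes(path: str | os.PathLike, genes: Iterable[Gene],
                     tf_attribute: str = "is_tf", cluster_attribute: str = "cluster_id") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.id}"]
            if g.is_tf:
                attrs.append(f"{tf_attribute}=true")
            if g.cluster_id:
                attrs.append(f"{cluster_attribute}={g.cluster_id}")
            fh.write(
                f"{g.contig}\tdualchip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                + ";".join(attrs) + "\n"
            )


# ---------------------------------------------------------------------------
# Aligned reads: BED6 and SAM
# ---------------------------------------------------------------------------


def read_bed_reads(path: str | os.PathLike) -> pd.DataFrame:
    """6-column BED of aligned fragments; name column holds the library key."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "library", "score", "strand"],
        dtype={"contig": str, "start": np.int64, "end": np.int64,
               "library": str, "strand": str},
    )
    return df[READ_COLUMNS]


def write_bed_reads(path: str | os.PathLike, reads) -> None:
    df = as_read_frame(reads)
    out = df[["contig", "start", "end", "library"]].copy()
    out["score"] = 0
    out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sam_reads(
    path: str | os.PathLike,
    library: str | None = None,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Aligned reads from SAM (text).  Library key from the RG ID unless given.

    Coordinates convert from SAM 1-based to 0-based half-open via pysam's
    ``reference_start`` / ``reference_end``.  Unmapped and sub-MAPQ records
    are dropped.
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        rg_map = {rg["ID"]: rg["ID"] for rg in sam.header.to_dict().get("RG", [])}
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                continue
            if library is not None:
                lib = library
            else:
                rg = aln.get_tag("RG") if aln.has_tag("RG") else None
                if rg is None or rg not in rg_map:
                    raise ValueError(
                        f"read {aln.query_name}: no RG tag and no library given"
                    )
                lib = rg_map[rg]
            rows.append(
                (aln.reference_name, aln.reference_start, aln.reference_end,
                 "-" if aln.is_reverse else "+", lib)
            )
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_sam_reads(path: str | os.PathLike, reads, genome: FusedGenome) -> None:
    """Write fragments as single-end SAM records with per-library read groups."""
    df = as_read_frame(reads)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in genome.contigs],
        "RG": [{"ID": lib, "SM": lib} for lib in sorted(df["library"].unique())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        tid = {c.name: i for i, c in enumerate(genome.contigs)}
        for i, r in enumerate(df.itertuples(index=False)):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"frag{i}"
            a.reference_id = tid[r.contig]
            a.reference_start = int(r.start)
            a.cigarstring = f"{int(r.end) - int(r.start)}M"
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            a.query_sequence = None
            a.set_tag("RG", r.library)
            sam.write(a)


# ---------------------------------------------------------------------------
# Interval / track writers
# ---------------------------------------------------------------------------


def write_bed_intervals(path: str | os.PathLike, intervals: Mapping[str, GenomicInterval]) -> None:
    """Named intervals (e.g. promoter windows) as BED6."""
    with open(path, "w") as fh:
        for name, iv in intervals.items():
            strand = iv.strand or "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def write_bedgraph(path: str | os.PathLike, contig: str, bin_size: int,
                   values: np.ndarray, contig_length: int | None = None) -> None:
    """Per-bin values as bedGraph, fixed-point with 4 decimals for stable files."""
    with open(path, "a") as fh:
        for i, v in enumerate(values):
            start = i * bin_size
            end = start + bin_size
            if contig_length is not None:
                end = min(end, contig_length)
            fh.write(f"{contig}\t{start}\t{end}\t{v:.4f}\n")
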