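import numpy as np
import pandas as pd
import pytest

from dualchip import Contig, Gene, build_fused_genome


@pytest.fixture
def toy_genome():
    """Two host contigs + one symbiont contig."""
    host = [Contig("chrI", 10_000, "host"), Contig("chrII", 8_000, "host")]
    sym = [Contig("plasmid", 5_000, "symbiont")]
    return build_fused_genome(host, sym)


@pytest.fixture
def toy_genes():
    return [
        Gene("g1", "chrI", 1_000, 3_000, "+"),
        Gene("g2", "chrI", 4_000, 5_500, "-"),
        Gene("g3", "chrII", 2_000, 4_000, "+"),
    ]


def make_reads(rows, library="mono:H3K9ac:1"):
    """rows: iterable of (contig, start, end[, strand[, library]])."""
    out = []
    for r in rows:
        contig, start, end = r[:3]
        strand = r[3] if len(r) > 3 else "+"
        lib = r[4] if len(r) > 4 else library
        out.append((contig, start, end, strand, lib))
    df = pd.DataFrame(out, columns=["contig", "start", "end", "strand", "library"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df
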