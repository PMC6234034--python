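"""Fused two-organism reference genome, gene models, and read/organism assignment.

ChIP-seq of a fungal host co-cultivated with a bacterial symbiont produces
libraries containing reads from both organisms.  Mapping against a *fused*
reference (host contigs concatenated with symbiont contigs) lets a single
alignment run classify every read by organism, so that downstream
normalization can be restricted to host-derived reads.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) and
SAM (1-based) are converted at the I/O boundary (:mod:`dualchip.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOST = "host"
SYMBIONT = "symbiont"
AMBIGUOUS = "ambiguous"


class Organism(str, Enum):
    host = HOST
    symbiont = SYMBIONT


@dataclass(frozen=True)
class Contig:
    """A chromosome/contig belonging to one of the two organisms."""

    name: str
    length: int
    organism: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.name!r}: length must be > 0")
        if self.organism not in (HOST, SYMBIONT):
            raise ValueError(f"contig {self.name!r}: unknown organism {self.organism!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a contig; ``clipped`` records boundary truncation."""

    contig: str
    start: int
    end: int
    strand: str | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Gene:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    is_tf: bool = False
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: invalid coordinates [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Annotated 5' end of the gene (transcription/translation start)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Annotated 3' end of the gene."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)


@dataclass(frozen=True)
class AlignedRead:
    """A single aligned fragment with its library labels."""

    contig: str
    start: int
    end: int
    strand: str
    condition: str
    target: str
    replicate: int

    @property
    def library(self) -> str:
        return f"{self.condition}:{self.target}:{self.replicate}"


def library_key(condition: str, target: str, replicate: int | str) -> str:
    return f"{condition}:{target}:{replicate}"


def parse_library_key(key: str) -> tuple[str, str, int]:
    condition, target, replicate = key.split(":")
    return condition, target, int(replicate)


@dataclass
class FusedGenome:
    """Two organisms' contigs in one linearized coordinate system.

    Host contigs come first, followed by symbiont contigs; ``offsets`` gives
    each contig's cumulative start in the linearized (fused) coordinates.
    """

    contigs: list[Contig]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate contig name: {dup!r}")
        if not self.offsets:
            off = 0
            for c in self.contigs:
                self.offsets[c.name] = off
                off += c.length
        self._by_name = {c.name: c for c in self.contigs}

    # -- lookups ---------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def contig(self, name: str) -> Contig:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def length(self, name: str) -> int:
        return self.contig(name).length

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def organism_of(self, name: str) -> str:
        return self.contig(name).organism

    def host_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.organism == HOST]

    def symbiont_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.organism == SYMBIONT]

    @property
    def host_length(self) -> int:
        return sum(c.length for c in self.host_contigs())

    # -- coordinate lift-over -------------------------------------------
    def to_fused(self, contig: str, pos: int) -> int:
        c = self.contig(contig)
        if not 0 <= pos < c.length:
            raise ValueError(f"position {pos} outside contig {contig!r} (length {c.length})")
        return self.offsets[contig] + pos

    def from_fused(self, fused_pos: int) -> tuple[str, int]:
        if not 0 <= fused_pos < self.total_length:
            raise ValueError(f"fused position {fused_pos} outside genome (length {self.total_length})")
        for c in self.contigs:
            off = self.offsets[c.name]
            if off <= fused_pos < off + c.length:
                return c.name, fused_pos - off
        raise AssertionError("unreachable: offsets cover the genome")

    def contig_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [c.name for c in self.contigs],
                "organism": [c.organism for c in self.contigs],
                "offset": [self.offsets[c.name] for c in self.contigs],
                "length": [c.length for c in self.contigs],
            }
        )


def build_fused_genome(
    host_contigs: Sequence[Contig], symbiont_contigs: Sequence[Contig]
) -> FusedGenome:
    """Concatenate host and symbiont contigs into a single fused reference.

    Host contigs precede symbiont contigs in the linearized order so every
    fused coordinate below the host block length is a host position.
    """
    contigs = [Contig(c.name, c.length, HOST) for c in host_contigs]
    contigs += [Contig(c.name, c.length, SYMBIONT) for c in symbiont_contigs]
    return FusedGenome(contigs)


def assign_organism(read: AlignedRead | GenomicInterval, genome: FusedGenome) -> str:
    """Classify a read as host / symbiont / ambiguous.

    Reads aligned to a native contig inherit that contig's organism.  Reads
    given in linearized fused coordinates (contig name ``"fused"``) may span
    a contig junction, in which case they are ``ambiguous`` and are excluded
    from every count.
    """
    if read.contig == "fused":
        c_start, _ = genome.from_fused(read.start)
        c_end, _ = genome.from_fused(read.end - 1)
        if c_start != c_end:
            return AMBIGUOUS
        return genome.organism_of(c_start)
    return genome.organism_of(read.contig)


def promoter_window(gene: Gene, upstream: int = 1000, downstream: int = 500,
                    contig_length: int | None = None) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    Covers ``upstream`` bp upstream through ``downstream`` bp downstream of
    the annotated TSS; clipped to contig bounds when ``contig_length`` is
    given, with the clipping recorded on the interval.  Windows may overlap
    neighboring genes; they are defined purely by distance from the TSS.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if contig_length is not None and end > contig_length:
        end, clipped = contig_length, True
    return GenomicInterval(gene.contig, start, end, gene.strand, clipped=clipped)


def promoter_windows(genes: Iterable[Gene], genome: FusedGenome | None = None,
                     upstream: int = 1000, downstream: int = 500) -> dict[str, GenomicInterval]:
    """Promoter windows for a gene collection, keyed by gene id."""
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        clen = genome.length(g.contig) if genome is not None else None
        out[g.id] = promoter_window(g, upstream, downstream, contig_length=clen)
    return out


# ---------------------------------------------------------------------------
# Vectorized read container
# ---------------------------------------------------------------------------

READ_COLUMNS = ["contig", "start", "end", "strand", "library"]


def reads_to_frame(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    """Convert AlignedRead objects to the columnar layout used by counting."""
    rows = [(r.contig, r.start, r.end, r.strand, r.library) for r in reads]
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def as_read_frame(reads) -> pd.DataFrame:
    """Accept either a read DataFrame or an iterable of AlignedRead."""
    if isinstance(reads, pd.DataFrame):
        missing = set(READ_COLUMNS) - set(reads.columns)
        if missing:
            raise ValueError(f"read frame missing columns: {sorted(missing)}")
        return reads
    return reads_to_frame(reads)


def classify_reads(reads, genome: FusedGenome) -> pd.Series:
    """Vectorized organism classification of a read frame."""
    df = as_read_frame(reads)
    org = {c.name: c.organism for c in genome.contigs}
    unknown = set(df["contig"].unique()) - set(org) - {"fused"}
    if unknown:
        raise KeyError(f"unknown contigs in reads: {sorted(unknown)}")
    out = df["contig"].map(org)
    fused_mask = df["contig"] == "fused"
    if fused_mask.any():
        sub = df.loc[fused_mask]
        out.loc[fused_mask] = [
            assign_organism(GenomicInterval("fused", s, e), genome)
            for s, e in zip(sub["start"], sub["end"])
        ]
    return out


def extend_reads(reads, genome: FusedGenome, fragment_length: int = 200) -> pd.DataFrame:
    """Extend each read from its 5' end to a fixed fragment length.

    Mimics fragment-level occupancy when only read ends were sequenced;
    ``fragment_length = 0`` disables extension.  Intervals are clipped to
    contig bounds.
    """
    df = as_read_frame(reads)
    if fragment_length <= 0:
        return df
    df = df.copy()
    lengths = df["contig"].map({c.name: c.length for c in genome.contigs})
    plus = df["strand"].to_numpy() != "-"
    start = df["start"].to_numpy(copy=True)
    end = df["end"].to_numpy(copy=True)
    end[plus] = start[plus] + fragment_length
    start[~plus] = end[~plus] - fragment_length
    df["start"] = np.maximum(start, 0)
    df["end"] = np.minimum(end, lengths.to_numpy())
    return df
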