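"""Gene anchors, anchored sequence windows, and gene-relative coordinates.

The screen works on the sequence flanking each gene's first exon: by default
20,000 bp upstream through 10,000 bp downstream of the 5' end of the first
annotated exon (the anchor).  Windows are oriented to the gene strand before
scanning, so upstream/downstream are biological directions, and hit
coordinates convert to gene-relative offsets with a GenBank-like convention:
the anchor base is +1, the base immediately upstream is -1, and there is no
position 0.

Coordinates are 0-based half-open internally.  Annotation parsing is backed
by gffutils; FASTA access accepts either a plain mapping of contig name to
sequence string or a pyfaidx.Fasta handle.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import gffutils

from .motifs import MotifHit, reverse_complement

__all__ = [
    "GeneAnchor",
    "AnchoredWindow",
    "parse_annotation",
    "extract_window",
    "to_gene_relative",
    "window_hit_to_genomic",
    "contig_length",
    "fetch",
]

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 20_000
DEFAULT_DOWNSTREAM = 10_000

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "primary_transcript"}


def contig_length(genome, seq_id: str) -> int:
    return len(genome[seq_id])


def fetch(genome, seq_id: str, start: int, end: int) -> str:
    """Plus-strand subsequence [start, end), uppercased; works for dicts and pyfaidx."""
    frag = genome[seq_id][start:end]
    return str(frag).upper()


@dataclass(frozen=True)
class GeneAnchor:
    """The 5' end of a gene's first annotated exon (0-based genomic)."""

    gene_id: str
    species: str
    seq_id: str
    strand: str
    anchor: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.anchor < 0:
            raise ValueError(f"gene {self.gene_id}: anchor must be >= 0")


@dataclass(frozen=True)
class AnchoredWindow:
    """An anchored window, oriented 5'->3' relative to its gene.

    ``start``/``end`` are the 0-based half-open genomic interval on the plus
    strand; ``sequence`` is reverse-complemented for minus-strand genes.
    ``upstream_extent`` counts oriented bases strictly before the anchor,
    ``downstream_extent`` counts the anchor base and everything after it.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    gene_strand: str
    sequence: str
    upstream_extent: int
    downstream_extent: int
    clipped_upstream: bool
    clipped_downstream: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("oriented sequence length must equal interval length")
        if self.upstream_extent + self.downstream_extent != self.end - self.start:
            raise ValueError("extents must sum to the interval length")

    @property
    def length(self) -> int:
        return self.end - self.start


def _first_exon_5prime(db: gffutils.FeatureDB, gene: gffutils.Feature) -> int | None:
    """0-based genomic position of the 5'-most exon start of the 5'-most transcript.

    Tie-breaks: among equally 5' transcripts, longest first exon, then
    lexicographic transcript id.  Genes whose exons hang directly off the
    gene feature are treated as a single transcript.
    """
    strand = gene.strand

    def five_prime(f) -> int:
        # gffutils is 1-based inclusive; convert to 0-based
        return f.start - 1 if strand == "+" else f.end - 1

    def most_5p(positions):
        return min(positions) if strand == "+" else max(positions)

    candidates = []  # (transcript_id, first_exon_5p, first_exon_len)
    for tx in db.children(gene, level=1):
        if tx.featuretype not in _TRANSCRIPT_TYPES:
            continue
        exons = list(db.children(tx, featuretype="exon"))
        if not exons:
            continue
        p = most_5p([five_prime(e) for e in exons])
        first = [e for e in exons if five_prime(e) == p]
        flen = max(e.end - e.start + 1 for e in first)
        candidates.append((tx.id, p, flen))

    if not candidates:
        exons = list(db.children(gene, featuretype="exon"))
        if not exons:
            return None
        return most_5p([five_prime(e) for e in exons])

    best_p = most_5p([p for _, p, _ in candidates])
    tied = [c for c in candidates if c[1] == best_p]
    tied.sort(key=lambda c: (-c[2], c[0]))
    return tied[0][1]


def parse_annotation(gff3_source: str, genome, species: str = "") -> list[GeneAnchor]:
    """Extract one first-exon anchor per gene from GFF3.

    ``gff3_source`` is a file path or raw GFF3 text.  Genes without exons are
    skipped with a warning; a contig named in the GFF3 but absent from the
    genome raises ``KeyError``.
    """
    if "\n" in gff3_source:
        from_string = True
    else:
        if not os.path.isfile(gff3_source):
            raise FileNotFoundError(gff3_source)
        from_string = False
    db = gffutils.create_db(
        gff3_source,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    anchors: list[GeneAnchor] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in _contig_names(genome):
            raise KeyError(f"contig {gene.seqid!r} in annotation absent from genome")
        pos = _first_exon_5prime(db, gene)
        if pos is None:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        anchors.append(
            GeneAnchor(
                gene_id=gene.id,
                species=species,
                seq_id=gene.seqid,
                strand=gene.strand,
                anchor=pos,
            )
        )
    return anchors


def _contig_names(genome):
    if hasattr(genome, "keys"):
        return set(genome.keys())
    return set(genome)  # pyfaidx.Fasta iterates records; fall back to __contains__ semantics


def extract_window(
    anchor: GeneAnchor,
    genome,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> AnchoredWindow:
    """Extract the oriented anchored window, clipping at contig boundaries.

    For a plus-strand gene the genomic interval is
    ``[anchor - upstream, anchor + downstream)``; for a minus-strand gene the
    mirror interval ``[anchor - downstream + 1, anchor + upstream + 1)``, with
    the sequence reverse-complemented so it reads 5'->3' along the gene.
    """
    clen = contig_length(genome, anchor.seq_id)
    if anchor.anchor >= clen:
        raise ValueError(f"anchor {anchor.anchor} beyond contig {anchor.seq_id} ({clen} bp)")
    if anchor.strand == "+":
        gstart, gend = anchor.anchor - upstream, anchor.anchor + downstream
    else:
        gstart, gend = anchor.anchor - downstream + 1, anchor.anchor + upstream + 1
    cstart, cend = max(0, gstart), min(clen, gend)
    seq = fetch(genome, anchor.seq_id, cstart, cend)
    if anchor.strand == "+":
        up_ext = anchor.anchor - cstart
        down_ext = cend - anchor.anchor
    else:
        seq = reverse_complement(seq)
        up_ext = cend - 1 - anchor.anchor
        down_ext = anchor.anchor - cstart + 1
    return AnchoredWindow(
        gene_id=anchor.gene_id,
        seq_id=anchor.seq_id,
        start=cstart,
        end=cend,
        gene_strand=anchor.strand,
        sequence=seq,
        upstream_extent=up_ext,
        downstream_extent=down_ext,
        clipped_upstream=up_ext < upstream,
        clipped_downstream=down_ext < downstream,
    )


def to_gene_relative(hit: MotifHit, window: AnchoredWindow) -> int:
    """Signed gene-relative offset of a hit's 5'-most oriented base.

    Anchor base = +1, base immediately upstream = -1; there is no 0.
    """
    if hit.start < 0 or hit.start + hit.length > len(window.sequence):
        raise ValueError(
            f"hit [{hit.start}, {hit.start + hit.length}) outside window of length {len(window.sequence)}"
        )
    d = hit.start - window.upstream_extent
    return d + 1 if d >= 0 else d


def window_hit_to_genomic(hit: MotifHit, window: AnchoredWindow) -> tuple[int, str]:
    """Map a window-coordinate hit to (plus-strand genomic start, genomic strand)."""
    if window.gene_strand == "+":
        gstart = window.start + hit.start
        strand = hit.strand
    else:
        gstart = window.end - hit.start - hit.length
        strand = "-" if hit.strand == "+" else "+"
    return gstart, strand
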