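"""Multi-species synthetic genomes with planted response elements.

Emulates the screen's input: per species one contig of i.i.d. background
sequence carrying a row of single-exon genes, with elements matching a given
pattern planted at known gene-relative offsets inside ortholog groups,
optionally corrupted by a fixed number of mismatches.  Every planted site is
recorded as a TruthRecord so recovery can be scored exactly, and the module
provides the closed-form expected background hit count used as the
false-positive oracle.

Background is i.i.d. per base (no higher-order composition), which keeps the
expectation closed-form.  Gene strands alternate +/- so both orientations of
the window machinery are exercised.  One RNG stream per species bundle,
derived from the recorded seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import motifs, regions
from .conservation import OrthologGroup
from .motifs import ResponseElementPattern, reverse_complement

__all__ = [
    "PlantSpec",
    "SyntheticSetConfig",
    "TruthRecord",
    "SpeciesBundle",
    "SyntheticBundle",
    "PlacementError",
    "sample_element",
    "generate_species_set",
    "expected_background_hits",
]

_BASES = "ACGT"
_FULL_SET = frozenset(_BASES)


class PlacementError(ValueError):
    """Raised when planted elements would collide."""


@dataclass(frozen=True)
class PlantSpec:
    """One element to plant per listed species, at a gene-relative offset.

    ``offsets`` maps species name -> signed offset of the element's 5'-most
    gene-oriented base (+1 convention, no position 0).  ``strand`` is the
    planting strand relative to the gene; ``n_mm`` corrupts the sampled
    element by exactly that many constrained-position mismatches.
    """

    group_id: str
    offsets: dict  # species -> signed offset
    n_mm: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.n_mm < 0:
            raise ValueError("corruption count must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if any(k == 0 for k in self.offsets.values()):
            raise ValueError("gene-relative offset 0 does not exist (+1 convention)")


@dataclass(frozen=True)
class SyntheticSetConfig:
    n_species: int = 3
    genes_per_species: int = 5
    upstream: int = regions.DEFAULT_UPSTREAM
    downstream: int = regions.DEFAULT_DOWNSTREAM
    gene_spacing: int = 42_000
    exon_length: int = 200
    composition: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.genes_per_species < 1:
            raise ValueError("counts must be positive")
        if self.gene_spacing <= 0 or self.exon_length <= 0:
            raise ValueError("layout lengths must be positive")
        if len(self.composition) != 4 or any(p < 0 for p in self.composition):
            raise ValueError("composition must be 4 non-negative probabilities")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1 within 1e-9")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def anchor_of(self, gene_index: int) -> int:
        return self.upstream + 1000 + gene_index * self.gene_spacing

    def gene_strand(self, gene_index: int) -> str:
        return "+" if gene_index % 2 == 0 else "-"

    @property
    def contig_length(self) -> int:
        return self.anchor_of(self.genes_per_species - 1) + self.upstream + 1001


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted element."""

    species: str
    gene_id: str
    group_id: str
    seq_id: str
    genomic_start: int
    genomic_strand: str
    gene_offset: int
    sequence: str  # pattern-oriented (reads 5'->3' as a pattern match)
    n_mm: int


@dataclass
class SpeciesBundle:
    species: str
    genome: dict  # seq_id -> sequence string
    gff3: str
    anchors: list


@dataclass
class SyntheticBundle:
    config: SyntheticSetConfig
    species: dict  # name -> SpeciesBundle
    orthologs: list
    truth: list
    manifest: dict

    def write(self, outdir) -> None:
        """Emit FASTA + GFF3 per species, ortholog TSV, truth TSV, manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, sb in self.species.items():
            with open(out / f"{name}.fasta", "w") as fh:
                for seq_id, seq in sb.genome.items():
                    fh.write(f">{seq_id}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
            (out / f"{name}.gff3").write_text(sb.gff3)
        with open(out / "orthologs.tsv", "w") as fh:
            fh.write("group_id\tspecies\tgene_id\n")
            for g in self.orthologs:
                for sp in sorted(g.members):
                    fh.write(f"{g.group_id}\t{sp}\t{g.members[sp]}\n")
        with open(out / "truth.tsv", "w") as fh:
            cols = [
                "species", "gene_id", "group_id", "seq_id", "genomic_start",
                "genomic_strand", "gene_offset", "sequence", "n_mm",
            ]
            fh.write("\t".join(cols) + "\n")
            for t in self.truth:
                fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
        with open(out / "manifest.txt", "w") as fh:
            for k, v in self.manifest.items():
                fh.write(f"{k}={v}\n")


def sample_element(
    pattern: ResponseElementPattern,
    n_mm: int,
    rng: np.random.Generator,
    composition=(0.25, 0.25, 0.25, 0.25),
) -> str:
    """Draw a word scoring exactly ``n_mm`` mismatches against ``pattern``.

    Constrained positions draw uniformly from their allowed set, spacer
    (unconstrained) positions from the background composition; then ``n_mm``
    distinct constrained positions are flipped to a disallowed base.
    """
    constrained = [i for i in range(pattern.length) if pattern.full.is_constrained(i)]
    if n_mm > len(constrained):
        raise ValueError(
            f"cannot plant {n_mm} mismatches: pattern has only {len(constrained)} constrained positions"
        )
    bases = []
    for i, s in enumerate(pattern.full.sets):
        if s == _FULL_SET:
            bases.append(_BASES[rng.choice(4, p=list(composition))])
        else:
            allowed = sorted(s)
            bases.append(allowed[rng.integers(len(allowed))])
    for i in rng.choice(len(constrained), size=n_mm, replace=False):
        pos = constrained[int(i)]
        disallowed = sorted(_FULL_SET - pattern.full.sets[pos])
        bases[pos] = disallowed[rng.integers(len(disallowed))]
    return "".join(bases)


def _plant_placement(config, plant, species, gene_index, pattern_len):
    """Genomic interval and window-oriented start for one planted element."""
    k = plant.offsets[species]
    up, down = config.upstream, config.downstream
    i0 = up + (k - 1 if k > 0 else k)  # window-oriented start index
    if i0 < 0 or i0 + pattern_len > up + down:
        raise ValueError(
            f"plant {plant.group_id}/{species}: offset {k} puts the element outside the window"
        )
    a = config.anchor_of(gene_index)
    if config.gene_strand(gene_index) == "+":
        gstart = a - up + i0
    else:
        gend = a + up + 1
        gstart = gend - i0 - pattern_len
    return gstart, i0


def _gff3_text(config: SyntheticSetConfig, species: str) -> str:
    lines = ["##gff-version 3"]
    for i in range(config.genes_per_species):
        a = config.anchor_of(i)
        strand = config.gene_strand(i)
        gid = f"{species}_g{i + 1}"
        if strand == "+":
            start1, end1 = a + 1, a + config.exon_length
        else:
            start1, end1 = a - config.exon_length + 2, a + 1
        for ftype, fid, parent in (
            ("gene", gid, None),
            ("mRNA", f"{gid}.t1", gid),
            ("exon", f"{gid}.t1.e1", f"{gid}.t1"),
        ):
            attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
            lines.append(f"chr1\tsim\t{ftype}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}")
    return "\n".join(lines) + "\n"


def generate_species_set(
    config: SyntheticSetConfig,
    plants: list,
    pattern: ResponseElementPattern | None = None,
    clean_background: bool = False,
    max_attempts: int = 100,
) -> SyntheticBundle:
    """Generate the multi-species bundle and its truth table.

    Deterministic for a fixed seed.  Planted sites must not overlap within a
    species (PlacementError lists the colliding specs).  With
    ``clean_background=True`` the background of each species is re-drawn
    (from a derived RNG stream) until scanning every gene window at the
    plants' maximum corruption budget recovers exactly the truth records —
    i.e. the bundle is certified free of spurious background matches.
    """
    pattern = pattern if pattern is not None else motifs.ir1_pattern()
    L = pattern.length
    species_names = config.species
    check_budget = max([p.n_mm for p in plants], default=0)

    # gene index per group: group og{j} <-> gene j-1 in every species
    def gene_index_of(group_id: str) -> int:
        idx = int(group_id[2:]) - 1
        if not 0 <= idx < config.genes_per_species:
            raise ValueError(f"group {group_id} has no corresponding gene")
        return idx

    # ortholog groups need >= 2 member species; single-species bundles get none
    orthologs = (
        [
            OrthologGroup(
                group_id=f"og{j + 1}",
                members={sp: f"{sp}_g{j + 1}" for sp in species_names},
            )
            for j in range(config.genes_per_species)
        ]
        if config.n_species >= 2
        else []
    )

    species_bundles: dict = {}
    truth: list[TruthRecord] = []

    for sidx, sp in enumerate(species_names):
        placements = []  # (gstart, plant, gene_index, window_start_index)
        for plant in plants:
            if sp not in plant.offsets:
                continue
            gidx = gene_index_of(plant.group_id)
            gstart, i0 = _plant_placement(config, plant, sp, gidx, L)
            placements.append((gstart, plant, gidx, i0))
        placements.sort(key=lambda x: x[0])
        for (s1, p1, *_), (s2, p2, *_) in zip(placements, placements[1:]):
            if s2 < s1 + L:
                raise PlacementError(
                    f"{sp}: plants {p1.group_id} and {p2.group_id} overlap "
                    f"(genomic starts {s1} and {s2}, length {L})"
                )

        for attempt in range(max_attempts):
            rng = np.random.default_rng([config.seed, sidx, attempt])
            arr = rng.choice(
                np.frombuffer(b"ACGT", dtype=np.uint8),
                size=config.contig_length,
                p=list(config.composition),
            )
            sp_truth: list[TruthRecord] = []
            for gstart, plant, gidx, i0 in placements:
                elem = sample_element(pattern, plant.n_mm, rng, config.composition)
                gene_strand = config.gene_strand(gidx)
                # plus-strand literal written into the contig
                oriented_as_gene = elem if plant.strand == "+" else reverse_complement(elem)
                literal = oriented_as_gene if gene_strand == "+" else reverse_complement(oriented_as_gene)
                arr[gstart : gstart + L] = np.frombuffer(literal.encode(), dtype=np.uint8)
                genomic_strand = gene_strand if plant.strand == "+" else ("-" if gene_strand == "+" else "+")
                sp_truth.append(
                    TruthRecord(
                        species=sp,
                        gene_id=f"{sp}_g{gidx + 1}",
                        group_id=plant.group_id,
                        seq_id="chr1",
                        genomic_start=gstart,
                        genomic_strand=genomic_strand,
                        gene_offset=plant.offsets[sp],
                        sequence=elem,
                        n_mm=plant.n_mm,
                    )
                )
            contig = arr.tobytes().decode("ascii")
            if not clean_background or _bundle_is_clean(
                config, contig, sp_truth, pattern, check_budget
            ):
                break
        else:
            raise RuntimeError(
                f"{sp}: no spurious-hit-free background found in {max_attempts} attempts"
            )

        species_bundles[sp] = SpeciesBundle(
            species=sp,
            genome={"chr1": contig},
            gff3=_gff3_text(config, sp),
            anchors=[
                regions.GeneAnchor(
                    gene_id=f"{sp}_g{i + 1}",
                    species=sp,
                    seq_id="chr1",
                    strand=config.gene_strand(i),
                    anchor=config.anchor_of(i),
                )
                for i in range(config.genes_per_species)
            ],
        )
        truth.extend(sp_truth)

    manifest = {
        "seed": config.seed,
        "n_species": config.n_species,
        "genes_per_species": config.genes_per_species,
        "contig_length": config.contig_length,
        "composition": ",".join(str(p) for p in config.composition),
        "upstream": config.upstream,
        "downstream": config.downstream,
        "pattern": pattern.full.to_bracket(),
        "n_plants": len(truth),
        "clean_background": clean_background,
    }
    return SyntheticBundle(
        config=config,
        species=species_bundles,
        orthologs=orthologs,
        truth=truth,
        manifest=manifest,
    )


def _bundle_is_clean(config, contig, sp_truth, pattern, budget) -> bool:
    """True when scanning every gene window recovers exactly the truth sites."""
    genome = {"chr1": contig}
    expected = {(t.gene_id, t.genomic_start) for t in sp_truth}
    found = set()
    for i in range(config.genes_per_species):
        gid_suffix = f"g{i + 1}"
        anchor = regions.GeneAnchor(
            gene_id=gid_suffix,
            species="",
            seq_id="chr1",
            strand=config.gene_strand(i),
            anchor=config.anchor_of(i),
        )
        window = regions.extract_window(
            anchor, genome, upstream=config.upstream, downstream=config.downstream
        )
        for h in motifs.scan(window.sequence, pattern, max_mm=budget, strands="both"):
            gstart, _ = regions.window_hit_to_genomic(h, window)
            # map gene_id back to the truth naming (species prefix stripped there)
            found.add((gid_suffix, gstart))
    expected_local = {(g.split("_", 1)[1], s) for g, s in expected}
    return found == expected_local


def expected_background_hits(
    pattern: ResponseElementPattern,
    length: int,
    composition=(0.25, 0.25, 0.25, 0.25),
) -> float:
    """Closed-form expected number of single-strand matches in i.i.d. background.

    Per start position the match probability is the product over pattern
    positions of the total composition probability of the allowed bases;
    multiplied by the number of start positions (length - pattern length + 1).
    For a self-reverse-complement pattern this single-strand value equals the
    canonical both-strand expectation.
    """
    L = pattern.length
    if length < L:
        raise ValueError("sequence length must be >= pattern length")
    comp = dict(zip(_BASES, composition))
    p_match = 1.0
    for s in pattern.full.sets:
        p_match *= sum(comp[b] for b in s)
    return (length - L + 1) * p_match
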