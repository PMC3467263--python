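"""Cross-species conservation filter over ortholog groups.

A candidate target gene is an ortholog group in which every member species
carries at least one element in its anchored window (presence mode), or
additionally at gene-relative positions within a configurable spread
(positional mode).  "Comparable position" has no single established
definition; presence is the least-assumptive default and the positional
tolerance (default 2,000 bp on gene-relative offsets) is an explicit,
documented interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .screen import ScreenHit, SpeciesHitTable

__all__ = [
    "OrthologGroup",
    "ConservedCandidate",
    "conserved_candidates",
    "read_ortholog_tsv",
    "write_candidates_tsv",
]

DEFAULT_TOLERANCE = 2_000


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: dict  # species -> gene_id

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"ortholog group {self.group_id} needs >= 2 species")


@dataclass(frozen=True)
class ConservedCandidate:
    group_id: str
    best_hits: dict  # species -> ScreenHit | None
    presence_all: bool
    positional_spread: int
    passes: bool


def _best_hit(hits: list[ScreenHit]) -> ScreenHit:
    # fewest mismatches; ties resolved to the 5'-most (smallest gene offset)
    return min(hits, key=lambda h: (h.mismatches, h.gene_offset))


def conserved_candidates(
    tables: list[SpeciesHitTable],
    orthologs: list[OrthologGroup],
    mode: str = "presence",
    tolerance: int = DEFAULT_TOLERANCE,
) -> list[ConservedCandidate]:
    """Intersect per-species hit tables over ortholog groups.

    presence mode: passes iff every member species has >= 1 hit anywhere in
    its window.  positional mode: additionally the maximum pairwise
    difference of best-hit gene-relative offsets must be <= tolerance.
    Output sorted by positional spread ascending (group id breaks ties).
    """
    if mode not in ("presence", "positional"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    if len(tables) < 2:
        raise ValueError("need hit tables for >= 2 species")
    by_species = {t.species: t for t in tables}

    out: list[ConservedCandidate] = []
    for group in orthologs:
        best: dict = {}
        for sp, gene_id in group.members.items():
            table = by_species.get(sp)
            hits = table.hits.get(gene_id, []) if table is not None else []
            best[sp] = _best_hit(hits) if hits else None
        present = [h for h in best.values() if h is not None]
        presence_all = len(present) == len(group.members)
        offsets = [h.gene_offset for h in present]
        spread = max(offsets) - min(offsets) if len(offsets) >= 2 else 0
        passes = presence_all and (mode == "presence" or spread <= tolerance)
        out.append(
            ConservedCandidate(
                group_id=group.group_id,
                best_hits=best,
                presence_all=presence_all,
                positional_spread=spread,
                passes=passes,
            )
        )
    out.sort(key=lambda c: (c.positional_spread, c.group_id))
    return out


def read_ortholog_tsv(path) -> list[OrthologGroup]:
    """Read group_id / species / gene_id rows (one row per membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        if sub["species"].duplicated().any():
            raise ValueError(f"ortholog group {gid}: a species appears more than once")
        groups.append(OrthologGroup(group_id=str(gid), members=dict(zip(sub["species"], sub["gene_id"]))))
    return groups


def write_candidates_tsv(candidates: list[ConservedCandidate], path) -> None:
    rows = []
    for c in candidates:
        for sp in sorted(c.best_hits):
            h = c.best_hits[sp]
            rows.append(
                {
                    "group_id": c.group_id,
                    "species": sp,
                    "gene_id": getattr(h, "gene_id", ""),
                    "gene_offset": h.gene_offset if h else "",
                    "mismatches": h.mismatches if h else "",
                    "presence_all": c.presence_all,
                    "positional_spread": c.positional_spread,
                    "passes": c.passes,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
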