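"""Gene-proximity annotation of called DMRs.

Each DMR is annotated with every gene whose interval lies within a maximum
edge-to-edge distance (default 15 kb).  Distance is 0 for overlapping
features; otherwise it is the gap between the closest interval edges,
signed by genomic direction (negative when the gene lies left of the DMR,
labelled "upstream"; positive/"downstream" when it lies right).  The sign
convention is genomic, not transcript-strand-relative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .containers import DMR, GeneInterval


@dataclass(frozen=True)
class GeneHit:
    """One gene within range of a DMR."""

    name: str
    distance: int
    relation: str  # overlaps | upstream | downstream


@dataclass(frozen=True)
class AnnotatedDMR:
    """A DMR plus its nearby genes, sorted by absolute distance."""

    dmr: DMR
    genes: tuple[GeneHit, ...]


def _gene_distance(dmr: DMR, gene: GeneInterval) -> tuple[int, str]:
    if gene.end < dmr.start:
        return gene.end - dmr.start, "upstream"
    if gene.start > dmr.end:
        return gene.start - dmr.end, "downstream"
    return 0, "overlaps"


def annotate_dmrs(dmrs: Sequence[DMR], genes: Sequence[GeneInterval],
                  max_distance: int = 15_000) -> list[AnnotatedDMR]:
    """List, per DMR, every gene within ``max_distance`` nucleotides.

    Genes are matched on the same chromosome only; hits are sorted by
    absolute distance (ties by gene name).  DMRs with no nearby gene carry
    an empty tuple.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end))

    out: list[AnnotatedDMR] = []
    for d in dmrs:
        hits = []
        for g in by_chrom.get(d.chrom, ()):
            if g.start > d.end + max_distance:
                break
            dist, relation = _gene_distance(d, g)
            if abs(dist) <= max_distance:
                hits.append(GeneHit(name=g.name, distance=dist,
                                    relation=relation))
        hits.sort(key=lambda h: (abs(h.distance), h.name))
        out.append(AnnotatedDMR(dmr=d, genes=tuple(hits)))
    return out


def annotation_strings(annotated: Sequence[AnnotatedDMR]) -> list[str]:
    """Human-readable per-DMR annotation column for TSV output."""
    out = []
    for a in annotated:
        out.append(";".join(f"{h.name}({h.relation}:{h.distance:+d})"
                            for h in a.genes) or ".")
    return out
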