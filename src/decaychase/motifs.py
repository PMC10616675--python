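"""AU-rich element (TTP-family binding site) scanner for 3'-UTR sequences.

The TTP family of tandem zinc-finger proteins binds AU-rich elements built
around the UAUUUAU core.  Four site classes are searched: the 7-mer
UAUUUAU, the 8-mer UAUUUUAU, and their U-flanked 9-mer (UUAUUUAUU) and
10-mer (UUAUUUUAUU) extensions.  Scanning is exact-match on the sense
strand (UTRs are already in mRNA orientation), case- and U/T-insensitive,
reports every occurrence including overlapping ones, and uses 1-based
inclusive coordinates throughout.  N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import normalize_sequence

__all__ = [
    "MOTIF_CLASSES",
    "SiteHit",
    "SiteAnnotation",
    "scan_sequence",
    "annotate_gene_set",
    "site_fraction",
]

#: Site classes, keyed by name, in increasing pattern length.
MOTIF_CLASSES: dict[str, str] = {
    "7-mer": "UAUUUAU",
    "8-mer": "UAUUUUAU",
    "9-mer": "UUAUUUAUU",
    "10-mer": "UUAUUUUAUU",
}


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence; coordinates are 1-based inclusive."""

    motif_class: str
    start: int
    end: int

    def contains(self, other: "SiteHit") -> bool:
        return self.start <= other.start and other.end <= self.end and self != other


@dataclass
class SiteAnnotation:
    """All site hits for one sequence (or the union over a gene's records)."""

    hits: list[SiteHit] = field(default_factory=list)

    @property
    def has_site(self) -> bool:
        return len(self.hits) > 0

    def class_counts(self, classes: Iterable[str] = MOTIF_CLASSES) -> dict[str, int]:
        return {c: sum(h.motif_class == c for h in self.hits) for c in classes}

    @property
    def maximal_sites(self) -> list[SiteHit]:
        """Hits not wholly contained in a longer hit."""
        return [h for h in self.hits if not any(o.contains(h) for o in self.hits)]


def scan_sequence(sequence: str, classes: Mapping[str, str] = MOTIF_CLASSES) -> SiteAnnotation:
    """Report every occurrence of every site class in one sequence.

    The input may be any case and use U or T; it is normalized before
    matching.  Overlapping occurrences are all reported.
    """
    seq = normalize_sequence(sequence)
    hits: list[SiteHit] = []
    for name, pattern in classes.items():
        start = seq.find(pattern)
        while start != -1:
            hits.append(SiteHit(motif_class=name, start=start + 1, end=start + len(pattern)))
            start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.start, h.end))
    return SiteAnnotation(hits=hits)


def annotate_gene_set(
    utrs: Mapping[str, str | list[str]], classes: Mapping[str, str] = MOTIF_CLASSES
) -> dict[str, SiteAnnotation]:
    """Scan every gene's UTR record(s); multiple records union their hits.

    Positions from later records follow those of earlier records in the
    hit list; ``has_site`` is true when any record carries any hit.
    """
    out: dict[str, SiteAnnotation] = {}
    for gene, seqs in utrs.items():
        ann = SiteAnnotation()
        for seq in [seqs] if isinstance(seqs, str) else seqs:
            ann.hits.extend(scan_sequence(seq, classes).hits)
        out[gene] = ann
    return out


def site_fraction(genes: Iterable[str], annotation: Mapping[str, SiteAnnotation]) -> float:
    """Fraction of a gene set carrying at least one site of any class.

    Genes absent from the annotation count as site-less.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("site_fraction: empty gene set")
    with_site = sum(1 for g in genes if g in annotation and annotation[g].has_site)
    return with_site / len(genes)
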