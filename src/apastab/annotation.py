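"""Gene-model container used throughout the pipeline.

Coordinates are 0-based half-open internally.  GTF round-trip converts to
1-based closed on write and back on read.  The annotation carries, besides
the usual gene/exon/intron structure, the attributes this pipeline consumes
directly: poly(A)-site (PAS) positions in the 3'-most exon, an optional
intronic PAS per intron, MaxEnt-style splice-site strength scores (consumed
as given, never computed here) and the genomic anchor of the 3'UTR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional


@dataclass
class Intron:
    """An intron with consumed splice-site strength scores.

    ``ipa_pas`` is the genomic position (last transcribed nucleotide) of an
    intronic PAS inside this intron, if any.
    """

    start: int
    end: int
    ss5_score: float = float("nan")
    ss3_score: float = float("nan")
    ipa_pas: Optional[int] = None

    @property
    def size(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Gene:
    """A gene model: ordered exons, introns, 3'-most-exon PAS positions.

    ``pas_positions`` are genomic coordinates of the last transcribed
    nucleotide of each cleavage site in the 3'-most exon.  ``utr3_anchor``
    is the genomic coordinate of the transcript-5' boundary of the 3'UTR
    (for a plus-strand gene the 3'UTR runs rightward from the anchor; for a
    minus-strand gene it runs leftward, anchor exclusive).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_type: str = "mRNA"
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)
    pas_positions: list[int] = field(default_factory=list)
    utr3_anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons.sort()

    @property
    def last_exon(self) -> tuple[int, int]:
        """Strand-aware 3'-most exon span."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the gene's 3' terminus (inclusive)."""
        return self.end - 1 if self.strand == "+" else self.start

    def utr3_span(self) -> Optional[tuple[int, int]]:
        """Genomic span of the 3'UTR out to the most distal PAS."""
        if self.utr3_anchor is None or not self.pas_positions:
            return None
        if self.strand == "+":
            return (self.utr3_anchor, max(self.pas_positions) + 1)
        return (min(self.pas_positions), self.utr3_anchor)

    def region_of(self, pos: int) -> tuple[str, Optional[int]]:
        """Classify a position within this gene.

        Returns ``(region_class, host_intron_index)`` where region_class is
        one of ``TPA`` (3'-most exon), ``IPA`` (intron), ``other_exonic``.
        """
        le = self.last_exon
        if le[0] <= pos < le[1]:
            return "TPA", None
        for i, intr in enumerate(self.introns):
            if intr.contains(pos):
                return "IPA", i
        for s, e in self.exons:
            if s <= pos < e:
                return "other_exonic", None
        return "intergenic", None


@dataclass
class GenomeAnnotation:
    """All gene models plus chromosome lengths."""

    chrom_lengths: dict[str, int]
    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterable[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def genes_at(self, chrom: str, strand: str, pos: int) -> list[Gene]:
        """Strand-matched genes whose span contains ``pos``."""
        return [
            g
            for g in self.genes
            if g.chrom == chrom and g.strand == strand and g.contains(pos)
        ]


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _fmt_attrs(**kw: object) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kw.items() if v is not None)


def write_gtf(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for chrom, length in sorted(ann.chrom_lengths.items()):
            fh.write(f"#!contig {chrom} {length}\n")
        for g in ann.genes:
            pas = ",".join(str(p) for p in g.pas_positions)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "apastab",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        _fmt_attrs(
                            gene_id=g.gene_id,
                            gene_type=g.gene_type,
                            pas_positions=pas,
                            utr3_anchor=g.utr3_anchor,
                        ),
                    ]
                )
                + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "apastab",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            _fmt_attrs(gene_id=g.gene_id),
                        ]
                    )
                    + "\n"
                )
            for intr in g.introns:
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "apastab",
                            "intron",
                            str(intr.start + 1),
                            str(intr.end),
                            ".",
                            g.strand,
                            ".",
                            _fmt_attrs(
                                gene_id=g.gene_id,
                                ss5_score=f"{intr.ss5_score:.4f}",
                                ss3_score=f"{intr.ss3_score:.4f}",
                                ipa_pas=intr.ipa_pas,
                            ),
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str) -> GenomeAnnotation:
    """Read a GTF written by :func:`write_gtf` back into the model."""
    chrom_lengths: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!contig"):
                _, chrom, length = line.split()
                chrom_lengths[chrom] = int(length)
                continue
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, feat, start, end, _sc, strand, _fr, attr_str = (
                line.rstrip("\n").split("\t")
            )
            attrs = dict(_ATTR_RE.findall(attr_str))
            gid = attrs["gene_id"]
            lo, hi = int(start) - 1, int(end)
            if feat == "gene":
                pas = [int(p) for p in attrs.get("pas_positions", "").split(",") if p]
                anchor = attrs.get("utr3_anchor")
                genes[gid] = Gene(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=lo,
                    end=hi,
                    gene_type=attrs.get("gene_type", "mRNA"),
                    pas_positions=pas,
                    utr3_anchor=int(anchor) if anchor is not None else None,
                )
                order.append(gid)
            elif feat == "exon":
                genes[gid].exons.append((lo, hi))
            elif feat == "intron":
                ipa = attrs.get("ipa_pas")
                genes[gid].introns.append(
                    Intron(
                        start=lo,
                        end=hi,
                        ss5_score=float(attrs.get("ss5_score", "nan")),
                        ss3_score=float(attrs.get("ss3_score", "nan")),
                        ipa_pas=int(ipa) if ipa is not None else None,
                    )
                )
    out = []
    for gid in order:
        g = genes[gid]
        g.exons.sort()
        g.introns.sort(key=lambda i: i.start)
        out.append(g)
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=out)
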