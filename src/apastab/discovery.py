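"""Poly(A)-site discovery from aligned 3'-end reads.

A read is called a PAS read when it carries two or more consecutive
non-genomic Ts at the start of its 5' soft-clip (read orientation) —
the reverse-complemented poly(A) tail — and maps with quality >= 10.
Cleavage sites are clustered within 24 nt by greedy summit absorption,
then assigned to strand-matched genes and classified by region
(3'-most exon = TPA, intron = IPA).

Strand convention: 3'-end reads are antisense to the transcript, so a
forward-strand record with a leading T clip reports a minus-strand
cleavage site at its alignment start, and a reverse-strand record (5'
clip stored as trailing As) reports a plus-strand site at its alignment
end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd
import pysam

from ._seq import revcomp
from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_WINDOW = 24
DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_CLIP_T = 2
MIN_ALIGNED_LENGTH = 23  # defensive; short reads are dropped upstream too


@dataclass
class AlignedRead:
    """Alignment facts needed for PAS calling (coordinates 0-based)."""

    read_id: str
    chrom: str
    strand: str  # alignment strand of the record
    ref_start: int
    ref_end: int
    mapq: int
    five_prime_softclip: str  # read orientation, 5'->3'

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedRead":
        cig = rec.cigartuples or []
        seq = rec.query_sequence or ""
        lead = cig[0][1] if cig and cig[0][0] == 4 else 0
        trail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
        if rec.is_reverse:
            clip5 = revcomp(seq[len(seq) - trail :]) if trail else ""
            strand = "-"
        else:
            clip5 = seq[:lead] if lead else ""
            strand = "+"
        return cls(
            read_id=rec.query_name or "",
            chrom=rec.reference_name or "",
            strand=strand,
            ref_start=rec.reference_start,
            ref_end=rec.reference_end or rec.reference_start,
            mapq=rec.mapping_quality,
            five_prime_softclip=clip5.upper(),
        )


@dataclass
class CleavageSite:
    """A cleavage position with per-sample read counts."""

    chrom: str
    strand: str  # transcript strand
    position: int  # last transcribed nucleotide, 0-based
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PASCluster:
    """Cleavage sites clustered within the window; summit = top site."""

    cluster_id: str
    chrom: str
    strand: str
    summit: int
    members: list[CleavageSite]
    counts: dict[str, int]
    gene_id: Optional[str] = None
    region_class: str = "intergenic"
    host_intron: int = -1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_nongenomic_5p_ts(read: AlignedRead, reference: Mapping[str, str]) -> int:
    """Consecutive Ts at the start of the read's 5' soft-clip that do not
    match the reference when the clip is laid back on the genome.

    A clip T matching the templated base (read in read orientation) is
    genomic and terminates the run.  Positions beyond the contig are
    treated as non-genomic (nothing to match).
    """
    clip = read.five_prime_softclip
    if not clip:
        return 0
    try:
        seq = reference[read.chrom]
    except KeyError:
        raise KeyError(f"no reference sequence for contig {read.chrom!r}")
    c = len(clip)
    n = 0
    for i, base in enumerate(clip):
        if base != "T":
            break
        if read.strand == "+":
            # leading clip: clip[i] occupies ref_start - (c - i)
            pos = read.ref_start - (c - i)
            genomic = 0 <= pos < len(seq) and seq[pos].upper() == "T"
        else:
            # read-orientation 5' clip of a reverse record extends right
            pos = read.ref_end + (c - 1 - i)
            genomic = 0 <= pos < len(seq) and seq[pos].upper() == "A"
        if genomic:
            break
        n += 1
    return n


def classify_read(
    read: AlignedRead,
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_t: int = DEFAULT_MIN_CLIP_T,
) -> Optional[tuple[str, str, int]]:
    """Return the (chrom, transcript strand, cleavage position) evidenced
    by this read, or None if it is not a PAS read.

    The cleavage site is the position of the read base adjacent to the 5'
    clip; the transcript strand is opposite to the alignment strand
    (antisense chemistry).
    """
    if read.mapq < min_mapq:
        return None
    if read.ref_end - read.ref_start < MIN_ALIGNED_LENGTH:
        return None
    if count_nongenomic_5p_ts(read, reference) < min_clip_t:
        return None
    if read.strand == "+":
        return (read.chrom, "-", read.ref_start)
    return (read.chrom, "+", read.ref_end - 1)


def call_pas_reads(
    reads: Iterable[AlignedRead],
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_t: int = DEFAULT_MIN_CLIP_T,
) -> Iterator[tuple[str, str, int]]:
    """Stream cleavage-site increments from PAS reads."""
    for read in reads:
        site = classify_read(read, reference, min_mapq, min_clip_t)
        if site is not None:
            yield site


def sites_from_sam(
    sam_paths: Mapping[str, str],
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_t: int = DEFAULT_MIN_CLIP_T,
) -> list[CleavageSite]:
    """Call PAS reads per sample (sample_id -> SAM path) and aggregate
    per-site, per-sample counts."""
    acc: dict[tuple[str, str, int], dict[str, int]] = {}
    for sample_id, path in sam_paths.items():
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                read = AlignedRead.from_pysam(rec)
                key = classify_read(read, reference, min_mapq, min_clip_t)
                if key is None:
                    continue
                acc.setdefault(key, {})[sample_id] = (
                    acc.get(key, {}).get(sample_id, 0) + 1
                )
    return [
        CleavageSite(chrom=c, strand=s, position=p, counts=cnt)
        for (c, s, p), cnt in sorted(acc.items())
    ]


def cluster_sites(
    sites: list[CleavageSite], window: int = DEFAULT_CLUSTER_WINDOW
) -> list[PASCluster]:
    """Greedy summit clustering within ``window`` nt.

    Repeatedly take the unassigned site with the highest total count
    (ties: smaller coordinate), absorb unassigned same-chrom/strand sites
    within ``window`` nt of it, and report the summit with summed counts.
    Deterministic; distinct same-strand summits end up > ``window`` nt
    apart.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    groups: dict[tuple[str, str], list[CleavageSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    clusters: list[PASCluster] = []
    for (chrom, strand), grp in sorted(groups.items()):
        order = sorted(range(len(grp)), key=lambda i: (-grp[i].total, grp[i].position))
        assigned = [False] * len(grp)
        for i in order:
            if assigned[i]:
                continue
            summit = grp[i]
            members = []
            for j in range(len(grp)):
                if not assigned[j] and abs(grp[j].position - summit.position) <= window:
                    assigned[j] = True
                    members.append(grp[j])
            members.sort(key=lambda s: s.position)
            counts: dict[str, int] = {}
            for m in members:
                for k, v in m.counts.items():
                    counts[k] = counts.get(k, 0) + v
            clusters.append(
                PASCluster(
                    cluster_id=f"{chrom}:{strand}:{summit.position}",
                    chrom=chrom,
                    strand=strand,
                    summit=summit.position,
                    members=members,
                    counts=counts,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.summit))
    return clusters


def assign_clusters(
    clusters: list[PASCluster], ann: GenomeAnnotation
) -> list[PASCluster]:
    """Assign each cluster to the strand-matched gene containing its
    summit and classify the region (TPA / IPA / other_exonic /
    intergenic).  Same-strand overlapping genes are resolved toward the
    gene with the closest 3' end (with a warning); unassigned clusters
    keep ``gene_id=None``.
    """
    for cl in clusters:
        genes = ann.genes_at(cl.chrom, cl.strand, cl.summit)
        if not genes:
            cl.gene_id = None
            cl.region_class = "intergenic"
            continue
        if len(genes) > 1:
            genes = sorted(genes, key=lambda g: abs(g.three_prime_end - cl.summit))
            logger.warning(
                "summit %s:%d matches %d same-strand genes; using %s",
                cl.chrom, cl.summit, len(genes), genes[0].gene_id,
            )
        gene = genes[0]
        region, host = gene.region_of(cl.summit)
        cl.gene_id = gene.gene_id
        cl.region_class = region
        cl.host_intron = host if host is not None else -1
    return clusters


def clusters_to_frame(clusters: list[PASCluster]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate clusters: (cluster metadata, cluster x sample counts)."""
    meta = pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "chrom": [c.chrom for c in clusters],
            "strand": [c.strand for c in clusters],
            "summit": [c.summit for c in clusters],
            "gene_id": [c.gene_id for c in clusters],
            "region_class": [c.region_class for c in clusters],
            "host_intron": [c.host_intron for c in clusters],
        }
    ).set_index("cluster_id")
    samples = sorted({s for c in clusters for s in c.counts})
    counts = pd.DataFrame(
        [[c.counts.get(s, 0) for s in samples] for c in clusters],
        index=meta.index,
        columns=samples,
        dtype=int,
    )
    return meta, counts


def write_bed(clusters: list[PASCluster], path: str) -> None:
    """BED6+2: chrom, start, end, cluster_id, total count, strand,
    gene_id, region_class.  Start/end delimit the member span."""
    with open(path, "w") as fh:
        for c in clusters:
            lo = min(m.position for m in c.members) if c.members else c.summit
            hi = max(m.position for m in c.members) if c.members else c.summit
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(lo),
                        str(hi + 1),
                        c.cluster_id,
                        str(c.total),
                        c.strand,
                        c.gene_id or ".",
                        c.region_class,
                    ]
                )
                + "\n"
            )
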