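"""Synthetic 3'-end sequencing data with known poly(A)-site kinetics.

Emulates the structure of a metabolic-labeling 3'-end-seq experiment:
several cell lines, each with total / 4sU-labeled / flow-through (FT)
fractions in replicate; genes carrying 1-3 cleavage sites in the 3'-most
exon and optionally one intronic site; first-order decay with a 1-hour
4sU pulse.  Under constant transcription at rate ``s`` and decay rate
``k``, steady-state abundance is ``s/k``, of which after a pulse of
length ``t`` the newly made (labeled) part is ``(s/k)(1 - exp(-k t))``
and the pre-existing (FT) part is ``(s/k) exp(-k t)``.  The stability
score log2(FT/4sU) is therefore ``log2(exp(-k t) / (1 - exp(-k t)))``,
a strictly decreasing function of ``k t``.

Reads are emitted as aligned SAM records using the antisense 3'-end-seq
convention: a read is sequenced from the transcript 3' end, so its
5' end carries the reverse-complemented poly(A) tail as a soft-clip of
Ts (in read orientation) and its first aligned base sits on the cleavage
site.  A plus-strand transcript hence yields a reverse-strand record
(stored trailing clip of As); a minus-strand transcript a forward record
(stored leading clip of Ts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import Gene, GenomeAnnotation, Intron

FRACTIONS = ("total", "4sU", "FT")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class KineticTruth:
    """Ground-truth kinetics of one isoform under the labeling model."""

    isoform_id: str
    synthesis_rate: float  # transcripts/hour
    decay_rate: float  # 1/hour
    labeling_time: float = 1.0  # hours

    def __post_init__(self) -> None:
        if self.synthesis_rate <= 0:
            raise ValueError("synthesis rate must be > 0")
        if self.decay_rate <= 0:
            raise ValueError("decay rate must be > 0")
        if self.labeling_time <= 0:
            raise ValueError("labeling time must be > 0")

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.decay_rate


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the emulated study design: 3 cell lines x
    {total, 4sU, FT} x 2 replicates; ~57% of genes with >1 3'UTR PAS;
    mRNA half-lives log-normal around 4 h; distal and intronic isoforms
    modestly less stable than proximal/terminal ones.
    """

    n_genes: int = 200
    pas_per_gene_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.43, 2: 0.37, 3: 0.20}
    )
    ipa_probability: float = 0.25
    autr_size_range: tuple[int, int] = (200, 2000)
    halflife_median: float = 4.0  # hours
    halflife_sigma: float = 0.8  # sigma of log half-life
    synthesis_median: float = 20.0
    synthesis_sigma: float = 1.0
    labeling_time: float = 1.0  # hours
    depth: int = 200_000  # expected reads per sample
    conditions: tuple[str, ...] = ("lineA", "lineB", "lineC")
    replicates: int = 2
    gene_type_probs: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.80, "lncRNA": 0.12, "pseudogene": 0.08}
    )
    gene_type_k_scale: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 1.0, "lncRNA": 2.5, "pseudogene": 1.8}
    )
    dpas_k_ratio: float = 1.3  # median k(dPAS)/k(pPAS) per step distal
    dpas_k_sigma: float = 0.25
    ipa_k_ratio: float = 2.0  # median k(IPA)/k(gene)
    ipa_k_sigma: float = 0.3
    utr3_gc_range: tuple[float, float] = (0.30, 0.70)
    intron_size_range: tuple[int, int] = (200, 5000)
    read_length: int = 50
    clip_len: int = 3
    microheterogeneity: int = 0
    decoy_fraction: float = 0.0
    lowmapq_fraction: float = 0.0
    contamination: float = 0.0  # cross-fraction leakage, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates <= 0 or self.depth < 0:
            raise ValueError("counts must be positive (depth may be 0)")
        for p in (self.ipa_probability, self.decoy_fraction, self.lowmapq_fraction,
                  self.contamination):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.pas_per_gene_probs.values()) - 1.0) > 1e-9:
            raise ValueError("pas_per_gene_probs must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# labeling model


def expected_fractions(
    synthesis_rate, decay_rate, labeling_time=1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady-state (total, labeled, unlabeled) abundances; vectorized.

    total = s/k; labeled = (s/k)(1-exp(-kt)); unlabeled = (s/k)exp(-kt).
    Conservation total = labeled + unlabeled holds exactly.
    """
    s = np.asarray(synthesis_rate, dtype=float)
    k = np.asarray(decay_rate, dtype=float)
    t = np.asarray(labeling_time, dtype=float)
    if np.any(k <= 0) or np.any(t <= 0):
        raise ValueError("decay rate and labeling time must be > 0")
    total = s / k
    unlabeled = total * np.exp(-k * t)
    labeled = total - unlabeled
    return total, labeled, unlabeled


def implied_stability_score(decay_rate, labeling_time=1.0) -> np.ndarray:
    """Noise-free stability score log2(FT/4sU) implied by the kinetics."""
    k = np.asarray(decay_rate, dtype=float)
    t = np.asarray(labeling_time, dtype=float)
    if np.any(k <= 0) or np.any(t <= 0):
        raise ValueError("decay rate and labeling time must be > 0")
    kt = k * t
    return (-kt / np.log(2.0)) - np.log2(-np.expm1(-kt))


# ---------------------------------------------------------------------------
# annotation + reference


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return int(lo)
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_annotation(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Generate gene models and a matching reference sequence.

    Genes are laid out sequentially on one chromosome (never overlapping,
    so gene assignment is unambiguous), each with a first exon, one intron
    (optionally housing an intronic PAS, with splice-site strength scores
    attached) and a 3'-most exon whose 3'UTR carries 1-3 PASs.  Per-gene
    3'UTR base composition (GC and U content) is drawn from the configured
    range so sequence-feature analyses have signal to find.  The few bases
    a poly(A)-tail soft-clip would occupy beyond each cleavage site are
    kept free of templated adenosines so that tail Ts are unambiguously
    non-genomic (the simulator does not model internal priming at genomic
    A-runs; decoy reads model priming noise instead).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = "chr1"
    cursor = 300
    genes: list[Gene] = []
    gene_meta: list[dict] = []
    n_pas_choices = sorted(config.pas_per_gene_probs)
    n_pas_p = np.array([config.pas_per_gene_probs[c] for c in n_pas_choices])
    gt_names = sorted(config.gene_type_probs)
    gt_p = np.array([config.gene_type_probs[t] for t in gt_names])

    for gi in range(config.n_genes):
        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_type = gt_names[rng.choice(len(gt_names), p=gt_p)]
        n_pas = int(n_pas_choices[rng.choice(len(n_pas_choices), p=n_pas_p)])
        has_ipa = rng.random() < config.ipa_probability

        exon1_len = int(rng.integers(150, 301))
        intron_len = _log_uniform_int(rng, *config.intron_size_range)
        cds2_len = int(rng.integers(100, 201))
        utr_anchor_loc = exon1_len + intron_len + cds2_len
        first_off = int(rng.integers(100, 301))
        pas_loc = [utr_anchor_loc + first_off]
        if n_pas > 1:
            total_autr = _log_uniform_int(rng, *config.autr_size_range)
            if n_pas == 2:
                gaps = [total_autr]
            else:
                u = rng.uniform(0.3, 0.7)
                g1 = max(1, int(round(total_autr * u)))
                gaps = [g1, max(1, total_autr - g1)]
            for g in gaps:
                pas_loc.append(pas_loc[-1] + g)
        tail = 12 + config.clip_len + config.microheterogeneity
        gene_len = pas_loc[-1] + 1 + tail
        start = cursor
        end = cursor + gene_len

        def to_genomic(loc: int) -> int:
            return start + loc if strand == "+" else end - 1 - loc

        def span_to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return (start + a, start + b)
            return (end - b, end - a)

        exon1 = span_to_genomic(0, exon1_len)
        intron_span = span_to_genomic(exon1_len, exon1_len + intron_len)
        exon2 = span_to_genomic(exon1_len + intron_len, gene_len)
        ipa_pos = None
        if has_ipa:
            ipa_loc = exon1_len + int(intron_len * rng.uniform(0.2, 0.8))
            ipa_pos = to_genomic(ipa_loc)
        intron = Intron(
            start=intron_span[0],
            end=intron_span[1],
            ss5_score=float(rng.normal(8.0, 2.0)),
            ss3_score=float(rng.normal(9.0, 2.0)),
            ipa_pas=ipa_pos,
        )
        pas_genomic = [to_genomic(p) for p in pas_loc]
        anchor = (
            start + utr_anchor_loc if strand == "+" else end - utr_anchor_loc
        )
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                gene_type=gene_type,
                exons=[exon1, exon2],
                introns=[intron],
                pas_positions=sorted(pas_genomic),
                utr3_anchor=anchor,
            )
        )
        gene_meta.append(
            {
                "gene_id": gene_id,
                "utr_gc": rng.uniform(*config.utr3_gc_range),
                "utr_u_share": rng.uniform(0.3, 0.7),
            }
        )
        cursor = end + int(rng.integers(250, 401))

    chrom_len = cursor + 300
    ann = GenomeAnnotation(chrom_lengths={chrom: chrom_len}, genes=genes)
    _check_no_same_strand_overlap(ann)
    seq = _build_reference(ann, gene_meta, chrom_len, config, rng)
    return ann, {chrom: seq}


def _check_no_same_strand_overlap(ann: GenomeAnnotation) -> None:
    by_key: dict[tuple[str, str], list[Gene]] = {}
    for g in ann:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for gs in by_key.values():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"same-strand overlap between {a.gene_id} and {b.gene_id}"
                )


def _build_reference(
    ann: GenomeAnnotation,
    gene_meta: list[dict],
    chrom_len: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> str:
    arr = rng.choice(_BASES, size=chrom_len)
    meta = {m["gene_id"]: m for m in gene_meta}
    guard = config.clip_len + config.microheterogeneity + 1
    for g in ann:
        m = meta[g.gene_id]
        gc, u = m["utr_gc"], m["utr_u_share"]
        span = g.utr3_span()
        if span is not None:
            lo, hi = span
            # sense-strand composition: G=C=gc/2, U=u*(1-gc), A=rest
            p_sense = np.array([(1 - u) * (1 - gc), gc / 2, gc / 2, u * (1 - gc)])
            p = p_sense if g.strand == "+" else p_sense[::-1].copy()
            arr[lo:hi] = rng.choice(_BASES, size=hi - lo, p=p)
        sites = list(g.pas_positions)
        for intr in g.introns:
            if intr.ipa_pas is not None:
                sites.append(intr.ipa_pas)
        non_a = np.frombuffer(b"CGT", dtype="S1")
        non_t = np.frombuffer(b"ACG", dtype="S1")
        for p_site in sites:
            if g.strand == "+":
                lo, hi = p_site - config.microheterogeneity, p_site + guard + 1
                zone = arr[max(lo, 0) + 1 : min(hi, chrom_len)]
                bad = zone == b"A"
                zone[bad] = rng.choice(non_a, size=int(bad.sum()))
            else:
                lo, hi = p_site - guard, p_site + config.microheterogeneity
                zone = arr[max(lo, 0) : min(hi, chrom_len)]
                bad = zone == b"T"
                zone[bad] = rng.choice(non_t, size=int(bad.sum()))
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# ground-truth kinetics


def simulate_truth(
    ann: GenomeAnnotation,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw per-isoform kinetics; one row per PAS isoform.

    Columns include the base decay rate ``k`` plus one ``k_<condition>``
    column per condition (initially all equal to ``k``); perturbation
    studies modify those columns before computing expected abundances.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    rows = []
    ln2 = math.log(2.0)
    for g in ann:
        half_life = float(
            np.exp(rng.normal(math.log(config.halflife_median), config.halflife_sigma))
        )
        k_gene = ln2 / half_life * config.gene_type_k_scale.get(g.gene_type, 1.0)
        s_gene = float(
            np.exp(rng.normal(math.log(config.synthesis_median), config.synthesis_sigma))
        )
        pas_sorted = sorted(
            g.pas_positions, reverse=(g.strand == "-")
        )  # proximal -> distal on the transcript
        shares = rng.dirichlet([2.0] * len(pas_sorted))
        k_iso = k_gene
        for rank, (pos, share) in enumerate(zip(pas_sorted, shares), start=1):
            if rank > 1:
                k_iso = k_iso * float(
                    np.exp(rng.normal(math.log(config.dpas_k_ratio), config.dpas_k_sigma))
                )
            rows.append(
                {
                    "isoform_id": f"{g.gene_id}:PAS{rank}",
                    "gene_id": g.gene_id,
                    "gene_type": g.gene_type,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "pas_pos": pos,
                    "region_class": "TPA",
                    "pas_rank": rank,
                    "host_intron": -1,
                    "intron_size": np.nan,
                    "ss5_score": np.nan,
                    "ss3_score": np.nan,
                    "s": max(s_gene * share, 1e-6),
                    "k": k_iso,
                }
            )
        for ii, intr in enumerate(g.introns):
            if intr.ipa_pas is None:
                continue
            k_ipa = k_gene * float(
                np.exp(rng.normal(math.log(config.ipa_k_ratio), config.ipa_k_sigma))
            )
            rows.append(
                {
                    "isoform_id": f"{g.gene_id}:IPA{ii + 1}",
                    "gene_id": g.gene_id,
                    "gene_type": g.gene_type,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "pas_pos": intr.ipa_pas,
                    "region_class": "IPA",
                    "pas_rank": 0,
                    "host_intron": ii,
                    "intron_size": float(intr.size),
                    "ss5_score": intr.ss5_score,
                    "ss3_score": intr.ss3_score,
                    "s": max(s_gene * rng.uniform(0.1, 0.6), 1e-6),
                    "k": k_ipa,
                }
            )
    truth = pd.DataFrame(rows).set_index("isoform_id")
    truth["half_life"] = ln2 / truth["k"]
    for cond in config.conditions:
        truth[f"k_{cond}"] = truth["k"]
    return truth


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """The (condition, fraction, replicate) axis of every count matrix."""
    rows = [
        {
            "sample_id": f"{cond}_{frac}_rep{rep}",
            "condition": cond,
            "fraction": frac,
            "replicate": rep,
        }
        for cond in config.conditions
        for frac in FRACTIONS
        for rep in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def expected_matrix(
    truth: pd.DataFrame,
    samples: pd.DataFrame,
    labeling_time: float = 1.0,
    contamination: float = 0.0,
) -> pd.DataFrame:
    """Expected abundance of each isoform in each sample (isoform x sample).

    ``contamination`` mixes the labeled and unlabeled pools symmetrically
    (a fraction of each pool ends up in the other fraction's library),
    modeling imperfect biotin pulldown; 0 by default.
    """
    out = {}
    for sample_id, row in samples.iterrows():
        k = truth[f"k_{row['condition']}"].to_numpy()
        total, labeled, unlabeled = expected_fractions(
            truth["s"].to_numpy(), k, labeling_time
        )
        x = contamination
        if row["fraction"] == "total":
            out[sample_id] = total
        elif row["fraction"] == "4sU":
            out[sample_id] = (1 - x) * labeled + x * unlabeled
        else:  # FT
            out[sample_id] = (1 - x) * unlabeled + x * labeled
    return pd.DataFrame(out, index=truth.index)


def simulate_counts(
    expected: pd.DataFrame,
    depth: int,
    rng: np.random.Generator,
    depth_jitter: float = 0.05,
) -> pd.DataFrame:
    """Multinomial read counts per sample with library sizes around depth.

    Library size per sample is Poisson around ``depth`` scaled by a
    log-normal jitter (sd ``depth_jitter`` on the log scale), emulating
    unequal sequencing yields across libraries.
    """
    if (expected.to_numpy() < 0).any():
        raise ValueError("expected abundances must be >= 0")
    counts = {}
    for sample_id in expected.columns:
        ab = expected[sample_id].to_numpy(dtype=float)
        tot = ab.sum()
        if depth == 0:
            counts[sample_id] = np.zeros(len(ab), dtype=int)
            continue
        if tot <= 0:
            raise ValueError(f"zero total abundance in sample {sample_id}")
        lib = int(
            rng.poisson(depth * float(np.exp(rng.normal(0.0, depth_jitter))))
        )
        counts[sample_id] = rng.multinomial(lib, ab / tot)
    return pd.DataFrame(counts, index=expected.index)


# ---------------------------------------------------------------------------
# SAM emission


def _sam_header(reference: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)} for chrom, seq in reference.items()
            ],
        }
    )


def simulate_alignments(
    counts: pd.Series,
    truth: pd.DataFrame,
    reference: Mapping[str, str],
    rng: np.random.Generator,
    read_length: int = 50,
    clip_len: int = 3,
    microheterogeneity: int = 0,
    decoy_fraction: float = 0.0,
    lowmapq_fraction: float = 0.0,
    mapq: int = 30,
    low_mapq: int = 3,
) -> list[pysam.AlignedSegment]:
    """Emit aligned reads for one sample's isoform counts.

    Real reads: first aligned base (read orientation) on the cleavage site
    (plus optional microheterogeneity jitter), read-orientation 5'
    soft-clip of ``clip_len`` Ts.  Decoy reads (a ``decoy_fraction`` of
    all emitted reads) align at random positions with 0-1 clipped Ts,
    mimicking internal-priming noise; they must not pass the >=2
    non-genomic-T calling rule.  A ``lowmapq_fraction`` of reads gets a
    mapping quality below 10.
    """
    header = _sam_header(reference)
    records: list[pysam.AlignedSegment] = []
    n_real = int(counts.sum())
    ridx = 0
    for iso_id, n in counts.items():
        n = int(n)
        if n == 0:
            continue
        row = truth.loc[iso_id]
        chrom, strand, pos = row["chrom"], row["strand"], int(row["pas_pos"])
        seq = reference[chrom]
        for _ in range(n):
            shift = (
                int(rng.integers(-microheterogeneity, microheterogeneity + 1))
                if microheterogeneity
                else 0
            )
            site = pos + shift
            q = low_mapq if rng.random() < lowmapq_fraction else mapq
            rec = _make_record(
                header, f"r{ridx}:{iso_id}", chrom, strand, site, seq,
                read_length, clip_len, q,
            )
            records.append(rec)
            ridx += 1
    if decoy_fraction > 0 and n_real > 0:
        n_decoy = int(round(n_real * decoy_fraction / (1.0 - decoy_fraction)))
        chroms = list(reference)
        for d in range(n_decoy):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = reference[chrom]
            site = int(rng.integers(200, len(seq) - 200))
            strand = "+" if rng.random() < 0.5 else "-"
            n_t = int(rng.integers(0, 2))  # 0 or 1 clipped T
            q = low_mapq if rng.random() < lowmapq_fraction else mapq
            rec = _make_record(
                header, f"decoy{d}", chrom, strand, site, seq,
                read_length, n_t, q,
            )
            records.append(rec)
    return records


def _make_record(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    strand: str,
    site: int,
    seq: str,
    read_length: int,
    clip_len: int,
    mapq: int,
) -> pysam.AlignedSegment:
    """One antisense 3'-end read whose first aligned base is ``site``."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = header.get_tid(chrom)
    rec.mapping_quality = mapq
    if strand == "+":
        # plus-strand transcript: reverse-strand record, trailing stored clip
        ref_start = site - read_length + 1
        if ref_start < 0 or site >= len(seq):
            raise ValueError(f"cleavage site {site} outside {chrom}")
        rec.flag = 16
        rec.reference_start = ref_start
        aligned = seq[ref_start : site + 1]
        rec.query_sequence = aligned + "A" * clip_len
        cig = [(0, read_length)] + ([(4, clip_len)] if clip_len else [])
        rec.cigartuples = cig
    else:
        # minus-strand transcript: forward record, leading stored T clip
        ref_end = site + read_length
        if site < 0 or ref_end > len(seq):
            raise ValueError(f"cleavage site {site} outside {chrom}")
        rec.flag = 0
        rec.reference_start = site
        aligned = seq[site:ref_end]
        rec.query_sequence = "T" * clip_len + aligned
        cig = ([(4, clip_len)] if clip_len else []) + [(0, read_length)]
        rec.cigartuples = cig
    return rec


def write_sam(
    records: Sequence[pysam.AlignedSegment],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write records to a plain-text SAM with @SQ headers."""
    header = _sam_header(reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_experiment(
    config: SimConfig,
) -> dict:
    """Full desk-scale experiment: annotation, reference, truth, counts.

    Returns a dict with keys ``annotation``, ``reference``, ``truth``,
    ``samples``, ``expected``, ``counts``.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ann, ref = simulate_annotation(config, rng)
    truth = simulate_truth(ann, config, rng)
    samples = sample_sheet(config)
    expected = expected_matrix(
        truth, samples, config.labeling_time, config.contamination
    )
    counts = simulate_counts(expected, config.depth, rng)
    return {
        "annotation": ann,
        "reference": ref,
        "truth": truth,
        "samples": samples,
        "expected": expected,
        "counts": counts,
    }
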