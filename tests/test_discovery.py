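"""PAS-read calling, cleavage-site clustering and gene assignment."""

import numpy as np
import pandas as pd
import pytest

from apastab import discovery, sim
from apastab.discovery import (
    AlignedRead,
    CleavageSite,
    assign_clusters,
    classify_read,
    cluster_sites,
    count_nongenomic_5p_ts,
)

# reference with no T in the laid-back zone of a forward read at pos 50
REF = {"chr1": "C" * 200}
REF_TRUN = {"chr1": "C" * 46 + "TTTT" + "C" * 150}  # Ts right before pos 50
REF_ARUN = {"chr1": "C" * 100 + "AAAA" + "C" * 96}  # As right after pos 99


def fwd_read(clip, ref_start=50, mapq=30, length=50):
    return AlignedRead(
        read_id="r", chrom="chr1", strand="+", ref_start=ref_start,
        ref_end=ref_start + length, mapq=mapq, five_prime_softclip=clip,
    )


def rev_read(clip, ref_end=100, mapq=30, length=50):
    return AlignedRead(
        read_id="r", chrom="chr1", strand="-", ref_start=ref_end - length,
        ref_end=ref_end, mapq=mapq, five_prime_softclip=clip,
    )


class TestNonGenomicTs:
    def test_ttta_clip_counts_three_leading_ts(self):
        assert count_nongenomic_5p_ts(fwd_read("TTTA"), REF) == 3
        assert classify_read(fwd_read("TTTA"), REF) == ("chr1", "-", 50)

    def test_single_t_is_below_threshold(self):
        assert count_nongenomic_5p_ts(fwd_read("TA"), REF) == 1
        assert classify_read(fwd_read("TA"), REF) is None

    def test_genomic_ts_terminate_the_run(self):
        # clip Ts match a templated T-run just upstream: genomic, not tail
        read = fwd_read("TT")
        assert count_nongenomic_5p_ts(read, REF_TRUN) == 0
        assert classify_read(read, REF_TRUN) is None

    def test_reverse_read_genomic_check_uses_a_run(self):
        # plus-strand transcript: clip Ts laid back read as complement of
        # the downstream reference; an A-run there makes them genomic
        read = rev_read("TT")
        assert count_nongenomic_5p_ts(read, REF_ARUN) == 0
        assert count_nongenomic_5p_ts(read, REF) == 2
        assert classify_read(read, REF) == ("chr1", "+", 99)

    def test_low_mapping_quality_is_rejected(self):
        assert classify_read(fwd_read("TTT", mapq=9), REF) is None
        assert classify_read(fwd_read("TTT", mapq=10), REF) is not None

    def test_short_alignment_is_rejected(self):
        assert classify_read(fwd_read("TTT", length=20), REF) is None

    def test_missing_contig_names_the_contig(self):
        read = AlignedRead("r", "chrX", "+", 50, 100, 30, "TTT")
        with pytest.raises(KeyError, match="chrX"):
            count_nongenomic_5p_ts(read, REF)

    def test_clip_beyond_contig_start_is_nongenomic(self):
        assert count_nongenomic_5p_ts(fwd_read("TTT", ref_start=1), REF) == 3


class TestSamRoundTrip:
    """The simulator's antisense encoding and the caller agree."""

    def test_plus_strand_site_recovered_from_reverse_record(self):
        ref = {"chr1": "G" * 300}
        rec = sim._make_record(
            sim._sam_header(ref), "r1", "chr1", "+", 150, ref["chr1"], 50, 3, 30
        )
        read = AlignedRead.from_pysam(rec)
        assert read.five_prime_softclip == "TTT"
        assert classify_read(read, ref) == ("chr1", "+", 150)

    def test_minus_strand_evidence_on_reference_reverse_side(self):
        ref = {"chr1": "G" * 300}
        rec = sim._make_record(
            sim._sam_header(ref), "r1", "chr1", "-", 150, ref["chr1"], 50, 3, 30
        )
        # forward record with leading (reference-left) soft clip of Ts
        assert not rec.is_reverse
        assert rec.cigartuples[0] == (4, 3)
        read = AlignedRead.from_pysam(rec)
        assert read.five_prime_softclip == "TTT"
        assert classify_read(read, ref) == ("chr1", "-", 150)


def make_sites(by_pos, strand="+"):
    return [
        CleavageSite("chr1", strand, pos, {"s": total})
        for pos, total in by_pos.items()
    ]


class TestClusterSites:
    def test_summit_absorbs_sites_within_window(self):
        clusters = cluster_sites(make_sites({100: 10, 110: 3, 140: 5}))
        got = {c.summit: c.total for c in clusters}
        assert got == {100: 13, 140: 5}

    def test_single_site_is_its_own_cluster(self):
        (c,) = cluster_sites(make_sites({77: 4}))
        assert c.summit == 77 and c.total == 4 and len(c.members) == 1

    def test_count_tie_breaks_to_smaller_coordinate(self):
        (c,) = cluster_sites(make_sites({100: 5, 112: 5}))
        assert c.summit == 100 and c.total == 10

    def test_strands_cluster_independently(self):
        sites = make_sites({100: 5}) + make_sites({105: 9}, strand="-")
        clusters = cluster_sites(sites)
        assert {(c.strand, c.summit) for c in clusters} == {("+", 100), ("-", 105)}

    def test_negative_window_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_sites([], window=-1)

    def test_conservation_and_separation_on_random_sites(self):
        rng = np.random.default_rng(8)
        pos = rng.choice(500, size=40, replace=False)
        sites = make_sites({int(p): int(rng.integers(1, 30)) for p in pos})
        clusters = cluster_sites(sites)
        assert sum(c.total for c in clusters) == sum(s.total for s in sites)
        summits = sorted(c.summit for c in clusters)
        assert all(b - a > 24 for a, b in zip(summits, summits[1:]))
        for c in clusters:
            assert all(abs(m.position - c.summit) <= 24 for m in c.members)


@pytest.fixture(scope="module")
def gene():
    cfg = sim.SimConfig(
        n_genes=1, pas_per_gene_probs={2: 1.0}, ipa_probability=1.0, seed=1
    )
    ann, _ = sim.simulate_annotation(cfg)
    return ann, ann.genes[0]


class TestAssignClusters:
    def _assign(self, ann, pos, strand):
        (c,) = assign_clusters(
            [discovery.PASCluster("x", "chr1", strand, pos, [], {})], ann
        )
        return c

    def test_summit_in_last_exon_is_tpa(self, gene):
        ann, g = gene
        c = self._assign(ann, g.pas_positions[0], g.strand)
        assert c.gene_id == g.gene_id and c.region_class == "TPA"

    def test_summit_in_intron_is_ipa_with_host(self, gene):
        ann, g = gene
        c = self._assign(ann, g.introns[0].ipa_pas, g.strand)
        assert c.region_class == "IPA" and c.host_intron == 0

    def test_summit_in_first_exon_is_other_exonic(self, gene):
        ann, g = gene
        first = g.exons[0] if g.strand == "+" else g.exons[-1]
        c = self._assign(ann, (first[0] + first[1]) // 2, g.strand)
        assert c.region_class == "other_exonic"

    def test_downstream_of_gene_end_is_intergenic(self, gene):
        ann, g = gene
        pos = g.end + 10 if g.strand == "+" else g.start - 10
        c = self._assign(ann, pos, g.strand)
        assert c.gene_id is None and c.region_class == "intergenic"

    def test_opposite_strand_gene_not_assigned(self, gene):
        ann, g = gene
        other = "-" if g.strand == "+" else "+"
        c = self._assign(ann, g.pas_positions[0], other)
        assert c.gene_id is None


class TestNoiseFreeRoundTrip:
    def test_called_sites_equal_simulated_truth(self, tmp_path):
        cfg = sim.SimConfig(
            n_genes=15, depth=4000, conditions=("lineA",), replicates=1, seed=21
        )
        exp = sim.simulate_experiment(cfg)
        rng = np.random.default_rng(5)
        paths = {}
        for s in exp["counts"].columns:
            recs = sim.simulate_alignments(
                exp["counts"][s], exp["truth"], exp["reference"], rng
            )
            p = tmp_path / f"{s}.sam"
            sim.write_sam(recs, exp["reference"], p)
            paths[s] = str(p)
        sites = discovery.sites_from_sam(paths, exp["reference"])
        clusters = cluster_sites(sites)
        got = {(c.chrom, c.strand, c.summit): c.counts for c in clusters}
        truth = exp["truth"]
        for iso, row in truth.iterrows():
            expected = exp["counts"].loc[iso]
            key = (row["chrom"], row["strand"], int(row["pas_pos"]))
            if expected.sum() == 0:
                assert key not in got
            else:
                assert got[key] == {
                    s: int(v) for s, v in expected.items() if v > 0
                }
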