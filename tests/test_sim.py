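"""Synthetic-data generator: labeling model, annotation, counts, reads."""

import math

import numpy as np
import pytest

from apastab import sim
from apastab.annotation import write_gtf


class TestExpectedFractions:
    def test_one_hour_half_life_splits_pools_evenly(self):
        total, labeled, unlabeled = sim.expected_fractions(
            math.log(2), math.log(2), 1.0
        )
        assert total == pytest.approx(1.0)
        assert labeled == pytest.approx(0.5)
        assert unlabeled == pytest.approx(0.5)
        # implied SS = log2(FT/4sU) = 0
        assert math.log2(unlabeled / labeled) == pytest.approx(0.0)

    def test_half_hour_half_life_implies_ss(self):
        # k = 2 ln2, t = 1: FT fraction 0.25, labeled 0.75
        total, labeled, unlabeled = sim.expected_fractions(1.0, 2 * math.log(2), 1.0)
        assert unlabeled / total == pytest.approx(0.25)
        assert labeled / total == pytest.approx(0.75)
        assert math.log2(unlabeled / labeled) == pytest.approx(-1.5849625007)
        assert sim.implied_stability_score(2 * math.log(2), 1.0) == pytest.approx(
            -1.5849625007
        )

    def test_conservation_exact_over_grid(self):
        ks = np.logspace(-2, 1, 25)
        total, labeled, unlabeled = sim.expected_fractions(3.7, ks, 1.0)
        np.testing.assert_array_equal(total, labeled + unlabeled)

    def test_slow_decay_limit_is_all_preexisting(self):
        total, _lab, unlab = sim.expected_fractions(1.0, 1e-9, 1.0)
        assert unlab / total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("k,t", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_rates_rejected(self, k, t):
        with pytest.raises(ValueError):
            sim.expected_fractions(1.0, k, t)

    def test_implied_ss_strictly_decreasing_in_k(self):
        ks = np.logspace(-2, 1, 50)
        ss = sim.implied_stability_score(ks, 1.0)
        assert np.all(np.diff(ss) < 0)


class TestKineticTruth:
    def test_half_life_is_ln2_over_k(self):
        kt = sim.KineticTruth("iso", synthesis_rate=2.0, decay_rate=math.log(2))
        assert kt.half_life == pytest.approx(1.0)

    @pytest.mark.parametrize("kw", [{"synthesis_rate": 0}, {"decay_rate": -1},
                                    {"labeling_time": 0}])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(isoform_id="iso", synthesis_rate=1.0, decay_rate=1.0)
        with pytest.raises(ValueError):
            sim.KineticTruth(**{**base, **kw})


class TestSimulateAnnotation:
    def test_config_forces_gene_structure(self):
        cfg = sim.SimConfig(
            n_genes=1, pas_per_gene_probs={2: 1.0}, ipa_probability=0.0, seed=4
        )
        ann, ref = sim.simulate_annotation(cfg)
        assert len(ann) == 1
        gene = ann.genes[0]
        assert len(gene.pas_positions) == 2
        assert all(i.ipa_pas is None for i in gene.introns)
        lo, hi = gene.last_exon
        assert all(lo <= p < hi for p in gene.pas_positions)

    def test_fixed_autr_range_forces_pas_distance(self):
        cfg = sim.SimConfig(
            n_genes=20, pas_per_gene_probs={2: 1.0}, autr_size_range=(500, 500),
            ipa_probability=0.0, seed=4,
        )
        ann, _ = sim.simulate_annotation(cfg)
        for gene in ann:
            a, b = sorted(gene.pas_positions)
            assert b - a == 500

    def test_same_seed_reproduces_annotation_and_sequence(self, tmp_path):
        cfg = sim.SimConfig(n_genes=10, seed=99)
        ann1, ref1 = sim.simulate_annotation(cfg)
        ann2, ref2 = sim.simulate_annotation(cfg)
        assert ref1 == ref2
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(ann1, str(p1))
        write_gtf(ann2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_genes_do_not_overlap_on_same_strand(self):
        cfg = sim.SimConfig(n_genes=50, seed=2)
        ann, _ = sim.simulate_annotation(cfg)
        for strand in "+-":
            spans = sorted(
                (g.start, g.end) for g in ann if g.strand == strand
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestSimulateCounts:
    def test_zero_depth_gives_all_zero_matrix(self, small_exp):
        rng = np.random.default_rng(0)
        counts = sim.simulate_counts(small_exp["expected"], 0, rng)
        assert (counts.to_numpy() == 0).all()

    def test_fixed_seed_reproduces_matrix(self, small_exp):
        c1 = sim.simulate_counts(
            small_exp["expected"], 10_000, np.random.default_rng(5)
        )
        c2 = sim.simulate_counts(
            small_exp["expected"], 10_000, np.random.default_rng(5)
        )
        assert c1.equals(c2)

    def test_large_depth_recovers_abundance_ratio(self):
        import pandas as pd

        expected = pd.DataFrame({"s1": [3.0, 1.0]}, index=["a", "b"])
        counts = sim.simulate_counts(
            expected, 400_000, np.random.default_rng(3), depth_jitter=0.0
        )
        ratio = counts.loc["a", "s1"] / counts.loc["b", "s1"]
        assert ratio == pytest.approx(3.0, rel=0.03)

    def test_zero_total_abundance_is_an_error(self):
        import pandas as pd

        expected = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero total abundance"):
            sim.simulate_counts(expected, 100, np.random.default_rng(0))


class TestSampleSheet:
    def test_axis_is_unique_and_complete(self):
        cfg = sim.SimConfig(n_genes=1)
        sheet = sim.sample_sheet(cfg)
        assert len(sheet) == 3 * 3 * 2  # conditions x fractions x replicates
        key = sheet[["condition", "fraction", "replicate"]].apply(tuple, axis=1)
        assert key.is_unique


class TestSimulateAlignments:
    def test_cleavage_site_outside_chromosome_is_an_error(self, small_exp):
        import pandas as pd

        truth = small_exp["truth"].head(1).copy()
        truth["pas_pos"] = 10  # too close to the contig start for a 50-nt read
        counts = pd.Series([1], index=truth.index)
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_alignments(
                counts, truth, small_exp["reference"], np.random.default_rng(0)
            )

    def test_truth_kinetics_are_positive(self, small_exp):
        truth = small_exp["truth"]
        assert (truth["s"] > 0).all()
        assert (truth["k"] > 0).all()
        assert np.allclose(truth["half_life"], math.log(2) / truth["k"])
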