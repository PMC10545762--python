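"""Synthetic community generator: invariants, determinism, sampling model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

import spikequant as sq
from spikequant.simulate import (
    CommunityDesign,
    GeneDesign,
    GenomeDesign,
    StandardDesign,
    build_community,
    simulate_sample,
    subsample_assignments,
)

from conftest import FOCAL, simulate_design


def _tiny_design(**kw) -> CommunityDesign:
    base = dict(
        genomes=(
            GenomeDesign("g1", FOCAL, FOCAL, 20_000, cells_per_liter=1e7),
        ),
        standards=(StandardDesign("s1", 10_000, 1e7),),
        total_reads=5_000,
        seed=1,
    )
    base.update(kw)
    return CommunityDesign(**base)


class TestBuildCommunity:
    def test_single_marker_locus_is_forced(self):
        genomes, _, truth = build_community(_tiny_design())
        (g,) = genomes
        assert sum(1 for x in g.genes if x.role == "marker") == 1
        assert truth.gene_copies["g1"]["marker"] == 1

    def test_amt_two_copy_genome_recorded_in_truth(self):
        """A genome designed with 2 ammonium transporters and no nitrate
        genes (the clade IV MAG gene complement) is reported as such."""
        design = _tiny_design(
            genomes=(
                GenomeDesign(
                    "syn", FOCAL, FOCAL, 20_000, cells_per_liter=1e7,
                    genes=(GeneDesign("ammonium_transporter", 1200, 2),),
                ),
            )
        )
        _, _, truth = build_community(design)
        copies = truth.gene_copies["syn"]
        assert copies["ammonium_transporter"] == 2
        assert copies["nitrate_reductase"] == 0
        assert copies["nitrite_transporter"] == 0

    def test_gene_intervals_within_bounds_and_disjoint(self):
        design = _tiny_design(
            genomes=(
                GenomeDesign(
                    "g", FOCAL, FOCAL, 12_000, cells_per_liter=1e7,
                    genes=(
                        GeneDesign("nitrate_reductase", 2100, 2),
                        GeneDesign("ammonium_transporter", 1200, 3),
                    ),
                ),
            )
        )
        (g,), _, _ = build_community(design)
        ordered = sorted(g.genes, key=lambda x: x.start)
        assert ordered[0].start >= 1 and ordered[-1].end <= g.length
        for a, b in zip(ordered, ordered[1:]):
            assert b.start > a.end
        assert g.length >= sum(x.length for x in g.genes)

    def test_oversized_gene_complement_rejected(self):
        design = _tiny_design(
            genomes=(
                GenomeDesign(
                    "g", FOCAL, FOCAL, 3_000, cells_per_liter=1e7,
                    genes=(GeneDesign("nitrate_reductase", 2_500, 2),),
                ),
            )
        )
        with pytest.raises(ValueError, match="exceed genome length"):
            build_community(design)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            build_community(CommunityDesign(genomes=(), standards=()))

    def test_identical_seeds_byte_identical(self):
        a = simulate_design(sq.default_design(seed=5, total_reads=20_000))
        b = simulate_design(sq.default_design(seed=5, total_reads=20_000))
        assert [g.sequence for g in a.genomes] == [g.sequence for g in b.genomes]
        assert [g.genes for g in a.genomes] == [g.genes for g in b.genomes]
        pd.testing.assert_frame_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.depths, b.depths)

    def test_different_seeds_differ(self):
        a = simulate_design(sq.default_design(seed=5, total_reads=20_000))
        b = simulate_design(sq.default_design(seed=6, total_reads=20_000))
        assert not a.assignments.equals(b.assignments)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=hst.integers(0, 2**16),
        narb=hst.integers(0, 2),
        amt=hst.integers(0, 3),
        length=hst.integers(10_000, 40_000),
    )
    def test_placement_invariants_hold_across_designs(self, seed, narb, amt, length):
        genes = tuple(
            GeneDesign(role, glen, copies)
            for role, glen, copies in (
                ("nitrate_reductase", 2100, narb),
                ("ammonium_transporter", 1200, amt),
            )
            if copies
        )
        design = _tiny_design(
            genomes=(
                GenomeDesign("g", FOCAL, FOCAL, length, cells_per_liter=1e7,
                             genes=genes),
            ),
            seed=seed,
        )
        (g,), _, truth = build_community(design)
        assert g.copy_count("nitrate_reductase") == narb
        assert g.copy_count("ammonium_transporter") == amt
        assert len(g.sequence) == length


class TestSimulateSample:
    def test_single_standard_conserves_reads_and_bases(self):
        design = _tiny_design(genomes=(), total_reads=4_000)
        g, s, t = build_community(design)
        reads, asn, dep = simulate_sample(g, s, t)
        assert len(asn) == 4_000
        assert (asn["subject_genome_id"] == "s1").all()
        assert dep["total_bases_mapped"].sum() == 4_000 * t.read_length
        assert len(reads) == 4_000
        assert all(len(r.seq) == t.read_length for r in reads[:50])

    def test_total_bases_conserved_in_mixture(self, community):
        t = community.truth
        assert (
            community.depths["total_bases_mapped"].sum()
            == t.total_reads * t.read_length
        )
        assert len(community.assignments) == t.total_reads

    def test_read_counts_multinomial_chi_square(self):
        """Reads per source follow a multinomial with probabilities
        proportional to molecules x length (goodness of fit at 1e5 reads,
        alpha = 0.001, over several seeds)."""
        pvals = []
        for seed in range(10):
            sim = simulate_design(sq.default_design(seed=seed, total_reads=100_000))
            t = sim.truth
            weights = np.array(
                [
                    (t.molecules_in_sample.get(g, 0) + t.molecules_added.get(g, 0))
                    * t.lengths[g]
                    for g in t.lengths
                ]
            )
            expected = weights / weights.sum() * t.total_reads
            observed = (
                sim.assignments.groupby("subject_genome_id")
                .size()
                .reindex(list(t.lengths), fill_value=0)
                .to_numpy()
            )
            pvals.append(sps.chisquare(observed, expected).pvalue)
        assert np.median(pvals) > 0.05
        assert all(p > 0.001 for p in pvals)

    def test_marker_read_fraction_matches_midpoint_expectation(self):
        """Under the midpoint rule with uniform full-length read starts, the
        expected fraction of a genome's reads hitting a gene of length l is
        exactly l / (L - rl + 1); pooled counts over 10 seeds must sit
        within 4 binomial sigma of it."""
        marker_hits = total = 0
        for seed in range(10):
            sim = simulate_design(_tiny_design(seed=seed, total_reads=20_000))
            g1 = sim.assignments.loc[sim.assignments["subject_genome_id"] == "g1"]
            marker_hits += int((g1["role"] == "marker").sum())
            total += len(g1)
        (genome,), _, truth = build_community(_tiny_design())
        p = genome.marker.length / (genome.length - truth.read_length + 1)
        sigma = np.sqrt(total * p * (1 - p))
        assert abs(marker_hits - total * p) < 4 * sigma

    def test_gene_reads_proportional_to_gene_length(self):
        """Two roles with a 2:1 total-length ratio on one genome receive
        reads in a 2:1 ratio (within sampling error) — no read-length edge
        term in the expectation."""
        design = _tiny_design(
            genomes=(
                GenomeDesign(
                    "g", FOCAL, FOCAL, 30_000, cells_per_liter=1e7,
                    genes=(
                        GeneDesign("nitrate_reductase", 2400, 1),
                        GeneDesign("ammonium_transporter", 1200, 1),
                    ),
                ),
            ),
            standards=(StandardDesign("s1", 10_000, 1e5),),
            total_reads=200_000,
            seed=3,
        )
        sim = simulate_design(design)
        counts = sim.assignments.loc[
            sim.assignments["subject_genome_id"] == "g"
        ].groupby("role").size()
        ratio = counts["nitrate_reductase"] / counts["ammonium_transporter"]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_zero_error_rate_gives_concordant_labels(self, community):
        asn, truth = community.assignments, community.truth
        assert (
            asn["taxon_a"] == asn["subject_genome_id"].map(truth.taxon_a)
        ).all()
        assert (
            asn["taxon_b"] == asn["subject_genome_id"].map(truth.taxon_b)
        ).all()

    def test_annotation_error_corrupts_one_system_at_stated_rate(self):
        sim = simulate_design(
            sq.default_design(seed=2, total_reads=50_000, annotation_error_rate=0.1)
        )
        asn, truth = sim.assignments, sim.truth
        bad_a = asn["taxon_a"] != asn["subject_genome_id"].map(truth.taxon_a)
        bad_b = asn["taxon_b"] != asn["subject_genome_id"].map(truth.taxon_b)
        assert not (bad_a & bad_b).any()  # exactly one system per corrupted read
        rate = (bad_a | bad_b).mean()
        assert rate == pytest.approx(0.1, rel=0.1)

    def test_zero_reads_rejected(self):
        g, s, t = build_community(_tiny_design())
        t.total_reads = 0
        with pytest.raises(ValueError):
            simulate_sample(g, s, t)

    def test_subsample_rebuilds_consistent_depths(self, two_mag):
        sub, dep = subsample_assignments(
            two_mag.assignments, two_mag.depths, two_mag.truth.read_length,
            0.5, rng=0,
        )
        assert len(sub) == pytest.approx(0.5 * len(two_mag.assignments), rel=0.02)
        counts = sub.groupby("subject_genome_id").size()
        for _, row in dep.iterrows():
            assert row["total_bases_mapped"] == (
                counts.get(row["reference_id"], 0) * two_mag.truth.read_length
            )
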