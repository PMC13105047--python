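"""Constitutive-intron selection rules, the boundary-comparison classifier
(including a brute-force oracle), and the summary tables."""

import numpy as np
import pandas as pd
import pytest

from rsplice import io as rio
from rsplice.io import SpliceJunction
from rsplice.junctions import (ClassifiedIntron, Intron, RS_CLASSES,
                               classify_junctions,
                               extract_constitutive_introns,
                               junction_length_summary,
                               motif_at_recursive_sites)


def _ann(transcripts):
    """transcripts: list of (tid, gid, chrom, strand, [(s,e), ...])."""
    ann = rio.GenomeAnnotation()
    for tid, gid, chrom, strand, exons in transcripts:
        ann.add(rio.TranscriptRecord(tid, gid, chrom, strand, sorted(exons)))
    return ann


def _intron(start, end, strand="+", pos="middle", chrom="chr1"):
    return Intron(chrom, start, end, strand, "g", "t", pos)


def _j(start, end, strand="+", reads=5, chrom="chr1", phase="nascent"):
    return SpliceJunction(chrom, start, end, strand, reads, phase=phase)


class TestConstitutiveExtraction:
    def test_isoform_specific_intron_discarded(self):
        # two isoforms share intron 201-300; the second isoform's exon spans
        # the isoform-specific intron 500-700 of the first
        ann = _ann([
            ("t1", "g1", "chr1", "+", [(100, 200), (301, 499), (701, 800)]),
            ("t2", "g1", "chr1", "+", [(100, 200), (301, 800)]),
        ])
        kept = {(i.start, i.end) for i in extract_constitutive_introns(ann)}
        assert kept == {(201, 300)}

    def test_overlapping_introns_of_different_genes_both_discarded(self):
        ann = _ann([
            ("t1", "g1", "chr1", "+", [(50, 99), (201, 250)]),
            ("t2", "g2", "chr1", "+", [(100, 149), (251, 300)]),
        ])
        # introns: 100-200 (g1) and 150-250 (g2) overlap each other
        assert extract_constitutive_introns(ann) == []

    def test_disjoint_introns_of_single_isoform_kept(self):
        ann = _ann([
            ("t1", "g1", "chr1", "+", [(1, 100), (201, 300), (401, 500)]),
        ])
        kept = extract_constitutive_introns(ann)
        assert [(i.start, i.end, i.position_class) for i in kept] == \
            [(101, 200, "first"), (301, 400, "last")]


class TestClassification:
    INTRON = _intron(1001, 5000, "+", "first")

    def classify(self, introns, nascent, mature=()):
        return classify_junctions(list(introns), list(nascent), list(mature))

    def test_rs5_junction(self):
        out, _ = self.classify([self.INTRON], [_j(1101, 5000)])
        (ci,) = out
        assert ci.rs_class == "RS5" and ci.recursive_5ss == 1101
        assert ci.recursive_3ss is None

    def test_exact_junction_is_basic(self):
        out, _ = self.classify([self.INTRON], [_j(1001, 5000)])
        (ci,) = out
        assert ci.rs_class == "basic"

    def test_recursive_site_within_75nt_discarded(self):
        out, log = self.classify([self.INTRON], [_j(1041, 5000)])
        assert out == []
        assert log.reason.tolist() == ["recursive_site_too_close"]

    def test_minus_strand_rs5(self):
        intron = _intron(1001, 5000, "-", "first")
        out, _ = self.classify([intron], [_j(1001, 4900, "-")])
        (ci,) = out
        assert ci.rs_class == "RS5" and ci.recursive_5ss == 4900

    def test_read_threshold(self):
        out, log = self.classify([self.INTRON], [_j(1101, 5000, reads=2)])
        assert out == []
        assert log.reason.tolist() == ["below_read_threshold"]

    def test_reads_summed_across_samples_of_same_phase(self):
        out, _ = self.classify(
            [self.INTRON], [_j(1101, 5000, reads=2), _j(1101, 5000, reads=2)])
        (ci,) = out
        assert ci.rs_class == "RS5"

    def test_junction_in_mature_cannot_be_recursive(self):
        out, log = self.classify([self.INTRON], [_j(1101, 5000)],
                                 [_j(1101, 5000, phase="mature")])
        assert out == []
        assert log.reason.tolist() == ["present_in_mature"]

    def test_exact_junction_may_appear_in_mature(self):
        out, _ = self.classify([self.INTRON], [_j(1001, 5000)],
                               [_j(1001, 5000, phase="mature")])
        assert out[0].rs_class == "basic"

    def test_unknown_strand_discarded(self):
        out, log = self.classify([self.INTRON], [_j(1101, 5000, ".")])
        assert out == []
        assert "unknown_strand" in log.reason.tolist()

    def test_rs_class_suppresses_basic_record(self):
        out, _ = self.classify([self.INTRON],
                               [_j(1001, 5000), _j(1101, 5000)])
        assert [ci.rs_class for ci in out] == ["RS5"]

    def test_nested_junction(self):
        out, _ = self.classify([self.INTRON], [_j(1101, 4900)])
        (ci,) = out
        assert ci.rs_class == "nested"
        assert (ci.recursive_5ss, ci.recursive_3ss) == (1101, 4900)

    def test_short_host_intron_rejected_for_rs(self):
        intron = _intron(1001, 1140, "+")  # 140 nt < 150
        out, log = self.classify([intron], [_j(1077, 1140)])
        assert out == []
        assert log.reason.tolist() == ["host_intron_too_short"]


def _oracle(intron, j_start, j_end, strand, reads, in_mature,
            min_reads=3, min_dist=75, min_rs_len=150, min_basic=75):
    """Independent enumeration of every boundary-comparison case."""
    if strand == "." or strand != intron.strand or reads < min_reads:
        return None
    if not (intron.start <= j_start and j_end <= intron.end):
        return None
    if (j_start, j_end) == (intron.start, intron.end):
        return "basic" if intron.length >= min_basic else None
    if in_mature:
        return None
    if intron.length < min_rs_len:
        return None
    left_inside = j_start > intron.start
    right_inside = j_end < intron.end
    if left_inside and (j_start - intron.start) < min_dist:
        return None
    if right_inside and (intron.end - j_end) < min_dist:
        return None
    if left_inside and right_inside:
        return "nested"
    if intron.strand == "+":
        return "RS5" if left_inside else "RS3"
    return "RS3" if left_inside else "RS5"


def test_classification_matches_brute_force_oracle():
    """Randomized equivalence on >= 1000 intron/junction pairs covering
    both strands, boundary equality, distance thresholds, read filters and
    mature-sample vetoes."""
    rng = np.random.default_rng(123)
    n_checked = 0
    for _ in range(1500):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(100, 10000))
        length = int(rng.integers(60, 3000))
        intron = _intron(start, start + length - 1, strand, "middle")
        # junction endpoints biased toward interesting boundary cases
        def endpoint(anchor, lo, hi):
            r = rng.random()
            if r < 0.3:
                return anchor
            if r < 0.6:
                return int(anchor + rng.integers(-120, 121))
            return int(rng.integers(lo, hi + 1))
        j_start = endpoint(intron.start, intron.start - 50, intron.end)
        j_end = endpoint(intron.end, j_start, intron.end + 50)
        if j_end < j_start:
            j_start, j_end = j_end, j_start
        j_strand = strand if rng.random() < 0.9 else \
            rng.choice(["+", "-", "."])
        reads = int(rng.integers(1, 10))
        in_mature = rng.random() < 0.3
        junction = _j(j_start, j_end, j_strand, reads)
        mature = [_j(j_start, j_end, j_strand, 1, phase="mature")] \
            if in_mature else []
        expected = _oracle(intron, j_start, j_end, j_strand, reads, in_mature)
        out, _ = classify_junctions([intron], [junction], mature)
        got = out[0].rs_class if out else None
        assert got == expected, (vars(intron), j_start, j_end, j_strand,
                                 reads, in_mature)
        n_checked += 1
    assert n_checked >= 1000


def test_bundle_classification_recovers_truth_exactly(bundle_small,
                                                      small_classified):
    """With read counts floored at the detection threshold, the classified
    RS labels and recursive-site coordinates equal the generator truth."""
    _, classified, log = small_classified
    truth = bundle_small.truth
    got = {}
    for ci in classified:
        got.setdefault(ci.intron.key, set()).add(ci.rs_class)
        ci.validate()  # post-hoc 75/150 invariants
    assert len(log) == 0
    for row in truth.itertuples():
        key = (row.chrom, row.start, row.end, row.strand)
        classes = got.get(key, set())
        if row.rs_class == "basic":
            assert classes == {"basic"}, key
        else:
            assert row.rs_class in classes and "basic" not in classes, key
    sites = {(ci.intron.key, ci.rs_class):
             (ci.recursive_5ss, ci.recursive_3ss) for ci in classified}
    for row in truth[truth.rs_class != "basic"].itertuples():
        key = (row.chrom, row.start, row.end, row.strand)
        r5, r3 = sites[(key, row.rs_class)]
        if not pd.isna(row.recursive_5ss):
            assert r5 == int(row.recursive_5ss)
        if not pd.isna(row.recursive_3ss):
            assert r3 == int(row.recursive_3ss)


class TestSummaries:
    def test_single_basic_intron_median(self):
        ci = ClassifiedIntron(_intron(1, 300, pos="first"), "basic",
                              supporting_junctions=[_j(1, 300)])
        df = junction_length_summary([ci])
        row = df[df.rs_class == "basic"].iloc[0]
        assert row.median_length == 300 and row.n_junctions == 1
        assert row.frac_first == 1.0

    def test_mean_of_three_lengths(self):
        cis = [ClassifiedIntron(_intron(1, 1000), "basic",
                                supporting_junctions=[_j(1, L)])
               for L in (100, 200, 300)]
        df = junction_length_summary(cis)
        assert df[df.rs_class == "basic"].iloc[0].mean_length == 200

    def test_empty_class_has_zero_count(self):
        df = junction_length_summary([])
        assert (df.n_junctions == 0).all()

    def test_rs_classes_prefer_first_introns_on_bundle(self,
                                                       large_classified):
        _, classified, _ = large_classified
        df = junction_length_summary(classified).set_index("rs_class")
        basic_frac = df.loc["basic", "frac_first"]
        for klass in ("RS5", "RS3"):
            assert df.loc[klass, "frac_first"] > basic_frac


def test_motif_fraction_matches_planted_aggu_rate(large_inputs,
                                                  large_classified,
                                                  bundle_large):
    """With 40% of planted sites degraded, ~60% of recursive 5'SS carry
    AGGU/C."""
    _, classified, _ = large_classified
    df = motif_at_recursive_sites(classified, large_inputs.genome)
    sub = df[(df.rs_class == "RS5") & (df.site_type == "recursive5")].iloc[0]
    assert sub.n_sites >= 400
    assert abs(sub.fraction_aggu
               - bundle_large.config.aggu_fraction) < 0.05
    empty = df[(df.site_type == "recursive3") & (df.rs_class == "RS5")]
    assert np.isnan(empty.iloc[0].fraction_aggu)
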