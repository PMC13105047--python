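"""RBNS matrix assembly, positional enrichment mapping and protein
ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rsplice.rbns import (PositionEnrichment, bin_kmer_fractions, load_rbns,
                          position_enrichment, rank_proteins)
from rsplice.topics import SiteSequence, vocabulary


def _table(entries):
    return pd.DataFrame(entries, columns=["protein", "concentration",
                                          "kmer", "R"])


def _full_table(proteins_conc, k=1, base=1.0):
    rows = []
    for prot, conc, scale in proteins_conc:
        for km in vocabulary(k):
            rows.append((prot, conc, km, base * scale))
    return _table(rows)


class TestLoadRbns:
    def test_concentration_with_highest_max_selected(self):
        rows = []
        for km in vocabulary(1):
            rows.append(("P1", "A", km, 1.0))
            rows.append(("P1", "B", km, 1.0))
        rows.append(("P1", "A", "A", 3.1))
        rows.append(("P1", "B", "A", 2.4))
        df = _table(rows).drop_duplicates(["protein", "concentration",
                                           "kmer"], keep="last")
        m = load_rbns(df)
        assert m.chosen_concentration["P1"] == "A"
        assert m.R.loc["P1", "A"] == 3.1

    def test_single_concentration_identity(self):
        m = load_rbns(_full_table([("P1", "A", 2.0)]))
        assert m.chosen_concentration["P1"] == "A"
        assert (m.R.loc["P1"] == 2.0).all()

    def test_missing_kmer_raises_naming_protein(self):
        df = _full_table([("P1", "A", 1.0)])
        df = df[df.kmer != "C"]
        with pytest.raises(ValueError, match="P1"):
            load_rbns(df)

    def test_mixed_k_lengths_raise(self):
        df = pd.concat([_full_table([("P1", "A", 1.0)], k=1),
                        _full_table([("P1", "A", 1.0)], k=2)])
        with pytest.raises(ValueError, match="mixed"):
            load_rbns(df)


def _span_seq(seq, span=75):
    assert len(seq) == 2 * span
    return SiteSequence("canonical5", "basic", "first", (-span, span - 1),
                        seq)


class TestPositionEnrichment:
    def test_uniform_r_gives_unit_enrichment(self):
        rng = np.random.default_rng(0)
        seqs = [_span_seq("".join(rng.choice(list("ACGT"), 150)))
                for _ in range(5)]
        m = load_rbns(_full_table([("P1", "A", 1.0)], k=1))
        pe = position_enrichment({"g": seqs}, m)
        assert np.allclose(pe.enrichment["g"].to_numpy(), 1.0)

    def test_toy_dot_product(self):
        # one bin of pure A/C mix: f = (0.75 A, 0.25 C), R = (2, 4) -> 2.5
        seq = ("AAAC" * 4)[:15] * 10
        seqs = [_span_seq(seq)]
        rows = [("P1", "A", "A", 2.0), ("P1", "A", "C", 4.0),
                ("P1", "A", "G", 1.0), ("P1", "A", "T", 1.0)]
        pe = position_enrichment({"g": seqs}, load_rbns(_table(rows)))
        # every 15-nt bin has 12 A and 3 C -> f=(0.8, 0.2), E = 2.4
        expected = 0.8 * 2.0 + 0.2 * 4.0
        assert np.allclose(pe.enrichment["g"].to_numpy()[:-1], expected)

    def test_matches_double_loop_oracle(self):
        """Matrix-product enrichment equals a naive loop to 1e-10."""
        rng = np.random.default_rng(42)
        k = 2
        vocab = vocabulary(k)
        seqs = [_span_seq("".join(rng.choice(list("ACGT"), 150)))
                for _ in range(8)]
        rows = [(f"P{p}", "A", km, float(rng.uniform(0.5, 5)))
                for p in range(3) for km in vocab]
        m = load_rbns(_table(rows))
        pe = position_enrichment({"g": seqs}, m)
        f = pe.fractions["g"]
        for b in f.index:
            for prot in m.R.index:
                naive = sum(f.loc[b, km] * m.R.loc[prot, km]
                            for km in vocab)
                assert abs(pe.enrichment["g"].loc[b, prot] - naive) < 1e-10

    def test_fraction_rows_stochastic(self):
        rng = np.random.default_rng(1)
        seqs = [_span_seq("".join(rng.choice(list("ACGT"), 150)))]
        f = bin_kmer_fractions(seqs, k=2)
        assert np.allclose(f.sum(axis=1), 1.0)

    def test_log2fc_sign_flips_on_group_swap(self):
        rng = np.random.default_rng(2)
        a = [_span_seq("".join(rng.choice(list("ACGT"), 150)))
             for _ in range(4)]
        b = [_span_seq("".join(rng.choice(list("ACGT"), 150)))
             for _ in range(4)]
        m = load_rbns(_table([("P1", "A", km, float(rng.uniform(1, 3)))
                              for km in vocabulary(1)]))
        p1 = position_enrichment({"a": a, "b": b}, m, pairs=[("a", "b")])
        p2 = position_enrichment({"a": a, "b": b}, m, pairs=[("b", "a")])
        assert np.allclose(p1.log2fc[("a", "b")].to_numpy(),
                           -p2.log2fc[("b", "a")].to_numpy())

    def test_short_window_raises(self):
        seqs = [SiteSequence("canonical5", "basic", "first", (-10, 9),
                             "A" * 20)]
        m = load_rbns(_full_table([("P1", "A", 1.0)], k=1))
        with pytest.raises(ValueError):
            position_enrichment({"g": seqs}, m)


class TestRankProteins:
    def _pe(self, tables):
        pe = PositionEnrichment(bins=[0], fractions={}, enrichment={})
        pe.log2fc = tables
        return pe

    def test_all_zero_scores_stable_name_order(self):
        t = pd.DataFrame(np.zeros((3, 3)), columns=["b", "c", "a"])
        df = rank_proteins(self._pe({("x", "y"): t}))
        assert df.protein.tolist() == ["a", "b", "c"]
        assert (df.max_abs_log2fc == 0).all()

    def test_single_strong_protein_ranks_first(self):
        t = pd.DataFrame({"p1": [0.1, -2.0], "p2": [0.0, 0.3]})
        df = rank_proteins(self._pe({("x", "y"): t}))
        assert df.protein.iloc[0] == "p1"
        assert df.max_abs_log2fc.iloc[0] == pytest.approx(2.0)

    def test_invariant_to_bin_order(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(6, 4)),
                         columns=list("abcd"))
        d1 = rank_proteins(self._pe({("x", "y"): t}))
        d2 = rank_proteins(self._pe({("x", "y"): t.iloc[::-1]}))
        pd.testing.assert_frame_equal(d1, d2)


def test_planted_cg_binder_enriched_at_motif_bins(large_inputs,
                                                  large_classified):
    """The CG-preferring pseudo-protein shows positive log2fc at canonical
    5'SS bins overlapping the planted -30..+50 motif window of RS introns."""
    from rsplice import pipeline as pl
    params = pl.PipelineParams(seed=7)
    _, classified, _ = large_classified
    pe, out = pl.stage_rbns(large_inputs, classified, params)
    fc = pe.log2fc[("canonical5_RS", "canonical5_basic")]["CGBIND1"]
    motif_bins = [b for b in fc.index if -30 <= b <= 30]
    assert (fc.loc[motif_bins] > 0.5).all()
    top = out["top_proteins"]
    assert top.protein.iloc[0] == "CGBIND1"
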