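"""Positional/grouped k-mer matrices, LDA mixture fits, topic expectations
and KL driving-k-mer ranking."""

import numpy as np
import pandas as pd
import pytest

from rsplice import io as rio
from rsplice.junctions import Intron
from rsplice.topics import (KmerCountMatrix, SiteSequence, TopicModel,
                            driving_kmers, extract_window, fit_mixture,
                            grouped_kmer_matrix, per_sequence_kmer_counts,
                            positional_kmer_matrix, sample_pseudo_aggu,
                            topic_expectations, vocabulary)


def _seqs(strings, window=None, site_type="canonical5", rs_class="basic",
          pos="first"):
    n = len(strings[0])
    window = window or (0, n - 1)
    return [SiteSequence(site_type, rs_class, pos, window, s)
            for s in strings]


class TestPositionalMatrix:
    def test_hand_enumerated_counts(self):
        mat = positional_kmer_matrix(_seqs(["AAGGTAAGGT"]), k=4,
                                     window_smooth=6)
        row = dict(zip(mat.vocab, mat.counts[0]))
        expected = {"AAGG": 2, "AGGT": 1, "GGTA": 1, "GTAA": 1, "TAAG": 1}
        assert {k: v for k, v in row.items() if v} == expected

    def test_smooth_one_counts_single_start(self):
        mat = positional_kmer_matrix(_seqs(["AAGGTAAGGT"]), k=4,
                                     window_smooth=1)
        assert len(mat.meta) == 7  # starts 0..6
        for d in range(7):
            assert mat.counts[d].sum() == 1

    def test_count_conservation_at_smooth_one(self):
        strings = ["ACGTACGTAGGTCCA", "TTTTACGCGCGCGCA"]
        mat = positional_kmer_matrix(_seqs(strings), k=4, window_smooth=1)
        total = per_sequence_kmer_counts(strings, 4).sum()
        assert mat.counts.sum() == total

    def test_planted_aggu_position_spread(self):
        """AGGU at offset -2 appears in exactly the documents whose
        smoothing window covers that start: p in {-7..-2} at smooth=6."""
        seq = "C" * 8 + "AGGT" + "C" * 9  # window -10..10, AGGT start at -2
        mat = positional_kmer_matrix(_seqs([seq], window=(-10, 10)), k=4,
                                     window_smooth=6)
        aggt = mat.vocab.index("AGGT")
        positive = sorted(mat.meta.position[mat.counts[:, aggt] > 0])
        assert positive == [-7, -6, -5, -4, -3, -2]

    def test_mismatched_windows_raise(self):
        seqs = _seqs(["ACGTACGT"]) + _seqs(["ACGTACGTAA"])
        with pytest.raises(ValueError):
            positional_kmer_matrix(seqs)


class TestGroupedMatrix:
    def test_thirty_sequences_two_documents(self):
        mat = grouped_kmer_matrix(_seqs(["ACGTACGTAC"] * 30), group_size=15,
                                  seed=0)
        assert len(mat.meta) == 2

    def test_remainder_dropped(self):
        mat = grouped_kmer_matrix(_seqs(["ACGTACGTAC"] * 31), group_size=15,
                                  seed=0)
        assert len(mat.meta) == 2

    def test_small_subtype_skipped_with_warning(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                grouped_kmer_matrix(_seqs(["ACGTACGTAC"] * 5),
                                    group_size=15, seed=0)

    def test_group_size_one_conserves_counts(self):
        strings = ["ACGTAGGTACGTT", "CCCGCGCGTATAT"] * 4
        mat = grouped_kmer_matrix(_seqs(strings), group_size=1, seed=1)
        per_seq = per_sequence_kmer_counts(strings, 4)
        assert mat.counts.sum(axis=0).tolist() == \
            per_seq.sum(axis=0).tolist()


def _degenerate_matrix(kmer="CGCG", n_docs=12, count=60):
    vocab = vocabulary(4)
    counts = np.zeros((n_docs, len(vocab)), dtype=np.int64)
    counts[:, vocab.index(kmer)] = count
    meta = pd.DataFrame({"doc": range(n_docs)})
    return KmerCountMatrix(counts, vocab, meta, 4)


class TestFitMixture:
    def test_degenerate_corpus_concentrates_one_topic(self):
        model = fit_mixture(_degenerate_matrix(), n_topics=6, seed=0)
        probs = model.topic_kmer_probs["CGCG"]
        top = probs.idxmax()
        assert probs[top] > 0.99
        assert (model.doc_topic_memberships.idxmax(axis=1) == top).all()

    def test_memberships_row_stochastic(self, grouped_model):
        _, model = grouped_model
        model.validate(atol=1e-8)

    def test_two_block_corpus_separates(self):
        vocab = vocabulary(4)
        counts = np.zeros((20, len(vocab)), dtype=np.int64)
        counts[:10, vocab.index("AAAA")] = 40
        counts[10:, vocab.index("TTTT")] = 40
        mat = KmerCountMatrix(counts, vocab,
                              pd.DataFrame({"doc": range(20)}), 4)
        model = fit_mixture(mat, n_topics=2, seed=1)
        dom = model.doc_topic_memberships.idxmax(axis=1)
        assert dom[:10].nunique() == 1 and dom[10:].nunique() == 1
        assert dom.iloc[0] != dom.iloc[-1]

    def test_all_zero_document_rejected(self):
        mat = _degenerate_matrix()
        mat.counts[3] = 0
        with pytest.raises(ValueError):
            fit_mixture(mat, seed=0)

    def test_seed_determinism(self):
        m1 = fit_mixture(_degenerate_matrix(), seed=5)
        m2 = fit_mixture(_degenerate_matrix(), seed=5)
        pd.testing.assert_frame_equal(m1.topic_kmer_probs,
                                      m2.topic_kmer_probs)


class TestTopicExpectations:
    def test_training_document_transform_consistency(self, grouped_model):
        matrix, model = grouped_model
        mem = topic_expectations(model, matrix.counts[:5])
        train = model.doc_topic_memberships.iloc[:5].to_numpy()
        assert np.abs(mem.to_numpy() - train).sum(axis=1).max() < 0.05

    def test_pure_kmer_vector_maps_to_its_topic(self):
        model = fit_mixture(_degenerate_matrix(), n_topics=6, seed=0)
        vocab = model.vocab
        vec = np.zeros(len(vocab), dtype=np.int64)
        vec[vocab.index("CGCG")] = 30
        mem = topic_expectations(model, vec)
        top = model.topic_kmer_probs["CGCG"].idxmax()
        assert mem.iloc[0][top] > 0.9

    def test_zero_vector_rejected(self, grouped_model):
        _, model = grouped_model
        with pytest.raises(ValueError):
            topic_expectations(model, np.zeros(len(model.vocab), dtype=int))

    def test_vocabulary_mismatch_rejected(self, grouped_model):
        _, model = grouped_model
        with pytest.raises(ValueError):
            topic_expectations(model, np.ones(10, dtype=int))


def _model_from_probs(probs: np.ndarray) -> TopicModel:
    vocab = [f"k{i}" for i in range(probs.shape[1])]
    topics = [f"topic{t + 1}" for t in range(probs.shape[0])]
    return TopicModel(
        n_topics=probs.shape[0], vocab=vocab,
        topic_kmer_probs=pd.DataFrame(probs, index=topics, columns=vocab),
        doc_topic_memberships=pd.DataFrame(np.ones((1, probs.shape[0]))
                                           / probs.shape[0]),
        meta=pd.DataFrame(), seed=0, bound=0.0, n_iter=0, lda=None)


class TestDrivingKmers:
    def test_identical_topics_score_zero(self):
        model = _model_from_probs(np.full((3, 4), 0.25))
        df = driving_kmers(model)
        assert np.allclose(df.kl_score, 0.0)

    def test_closed_form_value(self):
        # p=0.5 vs q=0.1: 0.5*ln(5) + 0.1 - 0.5 = 0.4047
        probs = np.array([[0.5, 0.5, 0.0, 0.0],
                          [0.1, 0.3, 0.3, 0.3]])
        df = driving_kmers(model := _model_from_probs(probs))
        val = df[(df.topic == "topic1") & (df.kmer == "k0")].kl_score.iloc[0]
        assert val == pytest.approx(0.5 * np.log(5) + 0.1 - 0.5, abs=1e-4)

    def test_scores_nonnegative_and_ranks_permutation(self, grouped_model):
        _, model = grouped_model
        df = driving_kmers(model)
        assert (df.kl_score >= -1e-12).all()
        for _, sub in df.groupby("topic"):
            assert sorted(sub["rank"]) == list(range(1, len(sub) + 1))

    def test_single_topic_rejected(self):
        with pytest.raises(ValueError):
            driving_kmers(_model_from_probs(np.array([[1.0, 0.0]])))


class TestPseudoAggu:
    def _genome(self, tmp_path, seq):
        fa = tmp_path / "g.fa"
        fa.write_text(f">c1\n{seq}\n")
        return rio.Genome(fa)

    def test_single_internal_aggt_found(self, tmp_path):
        intron = "GT" + "C" * 90 + "AGGT" + "C" * 90 + "AG"  # one internal site
        seq = "A" * 10 + intron + "A" * 10
        genome = self._genome(tmp_path, seq)
        intr = Intron("c1", 11, 10 + len(intron), "+", "g", "t", "first")
        out = sample_pseudo_aggu([intr], genome, 5, window=(-2, 2), seed=0)
        assert len(out) == 1
        # the site is the G starting the GU of the single internal AGGT
        assert out[0].site == intr.start + 94
        assert out[0].sequence == "AGGTC"

    def test_poly_a_intron_yields_empty(self, tmp_path):
        seq = "A" * 400
        genome = self._genome(tmp_path, seq)
        intr = Intron("c1", 50, 350, "+", "g", "t", "first")
        with pytest.warns(UserWarning):
            assert sample_pseudo_aggu([intr], genome, 5, seed=0) == []

    def test_draws_uniform_over_eligible_sites(self, tmp_path):
        from scipy import stats
        rng = np.random.default_rng(2)
        intron = "GT" + "".join(rng.choice(list("ACGT"), 1500)) + "AG"
        seq = "T" * 5 + intron + "T" * 5
        genome = self._genome(tmp_path, seq)
        intr = Intron("c1", 6, 5 + len(intron), "+", "g", "t", "first")
        counts = {}
        for s in range(1000):
            out = sample_pseudo_aggu([intr], genome, 1, window=(-2, 2),
                                     seed=s)
            counts[out[0].site] = counts.get(out[0].site, 0) + 1
        # enumeration oracle: all eligible AGGT starts
        eligible = [i for i in range(len(intron) - 3)
                    if intron[i:i + 4] == "AGGT"
                    and i + 2 >= 75 and len(intron) - (i + 3) >= 75]
        assert set(counts) <= {intr.start + i + 2 for i in eligible}
        observed = [counts.get(intr.start + i + 2, 0) for i in eligible]
        p = stats.chisquare(observed).pvalue
        assert p > 0.01


def test_extract_window_coordinates(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c1\n" + "ACGTACGTAC" * 2 + "\n")
    genome = rio.Genome(fa)
    # plus strand: window -2..+2 around site 10 -> bases 8..12
    assert extract_window(genome, "c1", "+", 10, (-2, 2)) == \
        genome.fetch("c1", 8, 12, "+")
    # minus strand: reverse complement of bases 8..12
    assert extract_window(genome, "c1", "-", 10, (-2, 2)) == \
        genome.fetch("c1", 8, 12, "-")
    # off-contig window dropped
    assert extract_window(genome, "c1", "+", 1, (-5, 5)) is None


def test_canonical_sites_carry_gu_ag(small_inputs, small_classified):
    """Position 0..1 of canonical 5'SS windows is GU for planted introns."""
    from rsplice.topics import extract_site_sequences
    _, classified, _ = small_classified
    seqs = extract_site_sequences(classified, small_inputs.genome,
                                  "canonical5", window=(-2, 2))
    assert seqs
    frac = np.mean([s.sequence[2:4] == "GT" for s in seqs])
    assert frac >= 0.99
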