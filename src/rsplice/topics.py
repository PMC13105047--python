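"""Positional k-mer composition matrices and latent-Dirichlet-allocation
mixture models around splice sites.

Two document designs are supported, mirroring the two ways the analysis
interrogates sequence composition:

* *positional*: one document per (site type, intron class, offset), counting
  tetramers whose start offsets fall in a sliding smoothing window — used to
  localise features relative to the splice site;
* *grouped*: documents are random groups of sequences from the same intron
  class with all tetramer positions pooled — used to score per-sequence
  topic expectations without over-fitting single sequences.

Topic distinctiveness is ranked by a Poisson-style Kullback-Leibler score of
each k-mer's probability in a topic against its mean probability in the
other topics.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from .io import Genome
from .junctions import ClassifiedIntron, Intron

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

DEFAULT_WINDOWS = {
    "canonical5": (-30, 50),
    "canonical3": (-50, 30),
    "recursive5": (-30, 50),
    "recursive3": (-50, 30),
    "pseudoAGGU": (-30, 50),
    "single": (-50, 50),
}


def vocabulary(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=np.int64)


def kmer_id_track(codes: np.ndarray, k: int) -> np.ndarray:
    """k-mer vocabulary index at each start offset; -1 where any base is
    ambiguous."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = 4 ** np.arange(k - 1, -1, -1)
    ids = (np.where(win < 0, 0, win) * weights).sum(axis=1)
    ids[(win < 0).any(axis=1)] = -1
    return ids


@dataclass(frozen=True)
class SiteSequence:
    site_type: str      # canonical5|canonical3|recursive5|recursive3|pseudoAGGU
    rs_class: str       # basic|RS5|RS3|nested|NA
    intron_position: str  # 'first' | 'downstream'
    window: tuple[int, int]  # offsets relative to the site (position 0)
    sequence: str       # sense strand, 5'->3' in transcription orientation
    chrom: str = ""
    strand: str = "+"
    site: int = 0       # genomic coordinate of position 0


@dataclass
class KmerCountMatrix:
    """Document x k-mer counts with per-document metadata."""

    counts: np.ndarray          # (n_docs, 4**k) non-negative integers
    vocab: list[str]
    meta: pd.DataFrame          # one row per document
    k: int

    def __post_init__(self):
        assert self.counts.shape == (len(self.meta), len(self.vocab))
        assert (self.counts >= 0).all()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.vocab,
                            index=self.meta.index)


# ---------------------------------------------------------------------------
# sequence extraction


def extract_window(genome: Genome, chrom: str, strand: str, site: int,
                   window: tuple[int, int]) -> str | None:
    """Sense-strand window around a genomic site; position 0 is the site
    base and positions increase 5'->3' in transcription orientation.
    Returns None when the window runs off the contig."""
    w0, w1 = window
    if strand == "+":
        lo, hi = site + w0, site + w1
    else:
        lo, hi = site - w1, site - w0
    if lo < 1 or hi > genome.contig_length(chrom):
        return None
    return genome.fetch(chrom, lo, hi, strand)


def _intron_position_label(position_class: str) -> str:
    return "first" if position_class == "first" else "downstream"


def extract_site_sequences(
        classified: list[ClassifiedIntron],
        genome: Genome,
        site_type: str,
        window: tuple[int, int] | None = None) -> list[SiteSequence]:
    """Windows around canonical or recursive splice sites of classified
    introns.  Sites truncated by contig edges are dropped (counted in a
    debug log)."""
    window = window or DEFAULT_WINDOWS[site_type]
    out: list[SiteSequence] = []
    dropped = 0
    for ci in classified:
        intr = ci.intron
        if site_type == "canonical5":
            site = intr.five_prime
        elif site_type == "canonical3":
            site = intr.three_prime
        elif site_type == "recursive5":
            site = ci.recursive_5ss
        elif site_type == "recursive3":
            site = ci.recursive_3ss
        else:
            raise ValueError(f"unknown site_type {site_type!r}")
        if site is None:
            continue
        seq = extract_window(genome, intr.chrom, intr.strand, site, window)
        if seq is None:
            dropped += 1
            continue
        out.append(SiteSequence(
            site_type=site_type, rs_class=ci.rs_class,
            intron_position=_intron_position_label(intr.position_class),
            window=window, sequence=seq, chrom=intr.chrom,
            strand=intr.strand, site=site))
    if dropped:
        log.debug("extract_site_sequences: dropped %d contig-edge sites",
                  dropped)
    return out


def sample_pseudo_aggu(introns: list[Intron], genome: Genome, n: int,
                       min_distance: int = 75,
                       window: tuple[int, int] = (-30, 50),
                       seed: int = 0) -> list[SiteSequence]:
    """Uniformly sampled internal AGGU occurrences as pseudo recursive 5'SS.

    Occurrences are located on the sense strand at least `min_distance` from
    both annotated splice sites; at most `n` are returned (seeded, without
    replacement)."""
    rng = np.random.default_rng(seed)
    eligible: list[tuple[Intron, int]] = []  # (intron, local site, 1-based)
    for intr in introns:
        if intr.length < 2 * min_distance + 1:
            continue
        seq = genome.fetch(intr.chrom, intr.start, intr.end, intr.strand)
        codes = encode(seq)
        ids = kmer_id_track(codes, 4)
        aggt = _CODE["A"] * 64 + _CODE["G"] * 16 + _CODE["G"] * 4 + _CODE["T"]
        for i in np.flatnonzero(ids == aggt):
            local_site = int(i) + 3  # 1-based position of the G starting GU
            if (local_site - 1 >= min_distance
                    and intr.length - local_site >= min_distance):
                eligible.append((intr, local_site))
    if not eligible:
        warnings.warn("sample_pseudo_aggu: no eligible AGGU occurrences")
        return []
    take = min(n, len(eligible))
    idx = rng.choice(len(eligible), size=take, replace=False)
    out = []
    for i in sorted(idx):
        intr, local = eligible[i]
        site = (intr.start + local - 1 if intr.strand == "+"
                else intr.end - local + 1)
        seq = extract_window(genome, intr.chrom, intr.strand, site, window)
        if seq is None:
            continue
        out.append(SiteSequence(
            site_type="pseudoAGGU", rs_class="NA",
            intron_position=_intron_position_label(intr.position_class),
            window=window, sequence=seq, chrom=intr.chrom,
            strand=intr.strand, site=site))
    return out


# ---------------------------------------------------------------------------
# count matrices


def _subtype_key(s: SiteSequence) -> tuple[str, str, str]:
    return (s.site_type, s.rs_class, s.intron_position)


def _stack_ids(seqs: list[SiteSequence], k: int) -> np.ndarray:
    return np.stack([kmer_id_track(encode(s.sequence), k) for s in seqs])


def positional_kmer_matrix(site_sequences: list[SiteSequence], k: int = 4,
                           window_smooth: int = 6) -> KmerCountMatrix:
    """One document per (subtype, position p): counts of k-mers whose start
    offsets lie in [p, p + window_smooth - 1], summed over all sequences of
    that subtype."""
    if not site_sequences:
        raise ValueError("no sequences")
    windows = {s.window for s in site_sequences}
    if len(windows) != 1:
        raise ValueError("all sequences must share the same window")
    w0, w1 = windows.pop()
    vocab = vocabulary(k)
    V = len(vocab)
    subtypes = sorted({_subtype_key(s) for s in site_sequences})
    docs, meta_rows = [], []
    for sub in subtypes:
        seqs = [s for s in site_sequences if _subtype_key(s) == sub]
        ids = _stack_ids(seqs, k)          # n x S start offsets
        S = ids.shape[1]
        per_start = np.zeros((S, V), dtype=np.int64)
        for s_off in range(S):
            col = ids[:, s_off]
            col = col[col >= 0]
            if len(col):
                per_start[s_off] = np.bincount(col, minlength=V)
        # document at position p sums starts p .. p+smooth-1
        n_docs = S - window_smooth + 1
        if n_docs <= 0:
            continue
        csum = np.vstack([np.zeros((1, V), dtype=np.int64),
                          np.cumsum(per_start, axis=0)])
        for d in range(n_docs):
            docs.append(csum[d + window_smooth] - csum[d])
            meta_rows.append({"site_type": sub[0], "rs_class": sub[1],
                              "intron_position": sub[2],
                              "position": w0 + d})
    meta = pd.DataFrame(meta_rows)
    return KmerCountMatrix(np.vstack(docs), vocab, meta, k)


def grouped_kmer_matrix(site_sequences: list[SiteSequence],
                        group_size: int = 15, k: int = 4,
                        seed: int = 0) -> KmerCountMatrix:
    """Documents are disjoint random groups of `group_size` sequences from
    the same subtype, with k-mer counts pooled over all positions.  The
    remainder of each subtype (and subtypes smaller than `group_size`) is
    dropped."""
    rng = np.random.default_rng(seed)
    vocab = vocabulary(k)
    V = len(vocab)
    subtypes = sorted({_subtype_key(s) for s in site_sequences})
    docs, meta_rows = [], []
    for sub in subtypes:
        seqs = [s for s in site_sequences if _subtype_key(s) == sub]
        if len(seqs) < group_size:
            warnings.warn(f"subtype {sub} has {len(seqs)} < "
                          f"{group_size} sequences; skipped")
            continue
        order = rng.permutation(len(seqs))
        n_groups = len(seqs) // group_size
        for gidx in range(n_groups):
            members = order[gidx * group_size:(gidx + 1) * group_size]
            counts = np.zeros(V, dtype=np.int64)
            for m in members:
                ids = kmer_id_track(encode(seqs[m].sequence), k)
                ids = ids[ids >= 0]
                if len(ids):
                    counts += np.bincount(ids, minlength=V)
            docs.append(counts)
            meta_rows.append({"site_type": sub[0], "rs_class": sub[1],
                              "intron_position": sub[2], "group": gidx})
    if not docs:
        raise ValueError("no subtype reached the group size")
    meta = pd.DataFrame(meta_rows)
    return KmerCountMatrix(np.vstack(docs), vocab, meta, k)


def per_sequence_kmer_counts(sequences: list[str], k: int = 4) -> np.ndarray:
    """One count row per sequence, pooling all (overlapping) positions."""
    V = 4 ** k
    out = np.zeros((len(sequences), V), dtype=np.int64)
    for i, seq in enumerate(sequences):
        ids = kmer_id_track(encode(seq), k)
        ids = ids[ids >= 0]
        if len(ids):
            out[i] = np.bincount(ids, minlength=V)
    return out


# ---------------------------------------------------------------------------
# mixture model


@dataclass
class TopicModel:
    """Fitted LDA mixture: row-stochastic topic x k-mer probabilities and
    document x topic grade-of-membership matrix."""

    n_topics: int
    vocab: list[str]
    topic_kmer_probs: pd.DataFrame    # topics x k-mers, rows sum to 1
    doc_topic_memberships: pd.DataFrame  # docs x topics, rows sum to 1
    meta: pd.DataFrame
    seed: int
    bound: float
    n_iter: int
    lda: LatentDirichletAllocation = field(repr=False)

    def validate(self, atol: float = 1e-8) -> None:
        assert self.n_topics >= 2
        for m in (self.topic_kmer_probs.to_numpy(),
                  self.doc_topic_memberships.to_numpy()):
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=atol)


def fit_mixture(matrix: KmerCountMatrix, n_topics: int = 6,
                seed: int = 0, max_iter: int = 500) -> TopicModel:
    """Batch variational LDA with symmetric priors 1/n_topics (documents)
    and 1/|vocab| (topics); deterministic given the seed."""
    X = matrix.counts
    if X.shape[0] < n_topics:
        raise ValueError("need at least n_topics documents")
    zero = X.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"{int(zero.sum())} all-zero documents; remove "
                         "them before fitting")
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=1.0 / n_topics,
        topic_word_prior=1.0 / len(matrix.vocab),
        learning_method="batch",
        max_iter=max_iter,
        mean_change_tol=1e-3,
        random_state=seed,
    )
    memberships = lda.fit_transform(X)
    topic_probs = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    topics = [f"topic{t + 1}" for t in range(n_topics)]
    model = TopicModel(
        n_topics=n_topics, vocab=matrix.vocab,
        topic_kmer_probs=pd.DataFrame(topic_probs, index=topics,
                                      columns=matrix.vocab),
        doc_topic_memberships=pd.DataFrame(memberships,
                                           columns=topics),
        meta=matrix.meta.reset_index(drop=True),
        seed=seed, bound=float(lda.bound_), n_iter=int(lda.n_iter_),
        lda=lda)
    model.validate()
    return model


def topic_expectations(model: TopicModel,
                       new_counts: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Posterior expected topic proportions for held-out count vectors."""
    if isinstance(new_counts, pd.DataFrame):
        if list(new_counts.columns) != model.vocab:
            raise ValueError("vocabulary mismatch")
        X = new_counts.to_numpy()
    else:
        X = np.asarray(new_counts)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.vocab):
            raise ValueError("vocabulary mismatch")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero count vector")
    mem = model.lda.transform(X)
    return pd.DataFrame(mem, columns=model.topic_kmer_probs.index)


def driving_kmers(model: TopicModel, floor: float = 1e-10) -> pd.DataFrame:
    """Rank each topic's k-mers by a Poisson-KL distinctiveness score
    p*ln(p/q) + q - p against q, the k-mer's mean probability in the other
    topics."""
    P = model.topic_kmer_probs.to_numpy()
    T = P.shape[0]
    if T < 2:
        raise ValueError("need at least two topics")
    rows = []
    for t in range(T):
        p = np.maximum(P[t], floor)
        q = np.maximum(P[np.arange(T) != t].mean(axis=0), floor)
        score = p * np.log(p / q) + q - p
        order = np.argsort(-score, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        for j, kmer in enumerate(model.vocab):
            rows.append({"topic": f"topic{t + 1}", "kmer": kmer,
                         "kl_score": float(score[j]),
                         "rank": int(ranks[j])})
    return pd.DataFrame(rows)
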