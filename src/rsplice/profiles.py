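"""GC metagene profiles, windowed GC distributions, tetramer enrichment
statistics and splice-site information content."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Genome, GenomeAnnotation
from .junctions import ClassifiedIntron
from .topics import SiteSequence, encode, kmer_id_track, vocabulary, \
    per_sequence_kmer_counts

SEGMENTS = ("upstream_exon", "intron", "downstream_exon")


def _gc_track(seq: str) -> np.ndarray:
    codes = encode(seq)
    return ((codes == 1) | (codes == 2)).astype(float)


def _binned(values: np.ndarray, bins: int) -> np.ndarray:
    """Length-normalize a per-base track into `bins` slices; sequences
    shorter than the bin count are linearly interpolated."""
    L = len(values)
    if L == 0:
        return np.full(bins, np.nan)
    if L >= bins:
        idx = np.floor(np.arange(L) * bins / L).astype(int)
        sums = np.bincount(idx, weights=values, minlength=bins)
        ns = np.bincount(idx, minlength=bins)
        return sums / ns
    x = np.linspace(0.0, 1.0, L)
    xq = np.linspace(0.0, 1.0, bins)
    return np.interp(xq, x, values)


def _flanking_exons(ann: GenomeAnnotation, ci: ClassifiedIntron
                    ) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Genomic intervals of the exons flanking the intron (upstream,
    downstream in transcription order)."""
    rec = ann.transcripts.get(ci.intron.transcript_id)
    if rec is None:
        return None
    intr = ci.intron
    for (s1, e1), (s2, e2) in zip(rec.exons, rec.exons[1:]):
        if e1 + 1 == intr.start and s2 - 1 == intr.end:
            if intr.strand == "+":
                return (s1, e1), (s2, e2)
            return (s2, e2), (s1, e1)
    return None


def metagene_gc(classified: list[ClassifiedIntron], ann: GenomeAnnotation,
                genome: Genome, bins: int = 50) -> pd.DataFrame:
    """Per rs_class and segment (upstream exon, intron, downstream exon, in
    transcription orientation): per-bin mean GC fraction over introns."""
    acc: dict[tuple[str, str], list[np.ndarray]] = {}
    for ci in classified:
        flanks = _flanking_exons(ann, ci)
        if flanks is None:
            continue
        up, down = flanks
        intr = ci.intron
        segs = {
            "upstream_exon": up,
            "intron": (intr.start, intr.end),
            "downstream_exon": down,
        }
        for name, (s, e) in segs.items():
            if e < s:
                continue
            seq = genome.fetch(intr.chrom, s, e, intr.strand)
            acc.setdefault((ci.rs_class, name), []).append(
                _binned(_gc_track(seq), bins))
    rows = []
    for (klass, seg), tracks in sorted(acc.items()):
        mat = np.vstack(tracks)
        means = np.nanmean(mat, axis=0)
        for b in range(bins):
            rows.append({"rs_class": klass, "segment": seg, "bin": b,
                         "mean_gc": float(means[b]), "n": len(tracks)})
    return pd.DataFrame(rows)


def window_gc(site_sequences: list[SiteSequence]) -> pd.DataFrame:
    """One GC fraction per sequence, with its class labels."""
    rows = []
    for s in site_sequences:
        rows.append({
            "site_type": s.site_type, "rs_class": s.rs_class,
            "intron_position": s.intron_position,
            "gc": float(_gc_track(s.sequence).mean()),
        })
    return pd.DataFrame(rows)


def tetramer_enrichment(group_a_seqs: list[str],
                        group_b_seqs: list[str], k: int = 4) -> pd.DataFrame:
    """Per k-mer occurrence enrichment between two sequence groups.

    log2fc uses a Haldane 0.5 pseudo-count on the counts; the p-value is a
    two-sided Fisher's exact test of the k-mer vs all-other-k-mer counts;
    q-values are Benjamini-Hochberg.
    """
    if not group_a_seqs or not group_b_seqs:
        raise ValueError("both groups must be non-empty")
    ca = per_sequence_kmer_counts(group_a_seqs, k).sum(axis=0)
    cb = per_sequence_kmer_counts(group_b_seqs, k).sum(axis=0)
    tot_a, tot_b = int(ca.sum()), int(cb.sum())
    vocab = vocabulary(k)
    log2fc = (np.log2((ca + 0.5) / tot_a) - np.log2((cb + 0.5) / tot_b))
    pvals = np.ones(len(vocab))
    for i in range(len(vocab)):
        table = [[int(ca[i]), tot_a - int(ca[i])],
                 [int(cb[i]), tot_b - int(cb[i])]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "kmer": vocab, "count_a": ca, "count_b": cb,
        "log2fc": log2fc, "p_value": pvals, "q_value": qvals,
    })


def pwm_information(sequences: list[str],
                    pseudo: float = 1e-6) -> pd.DataFrame:
    """Per-position information content (bits, uniform background):
    IC = 2 + sum_b f_b log2 f_b."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    L = lengths.pop()
    mat = np.stack([encode(s) for s in sequences])
    rows = []
    for pos in range(L):
        col = mat[:, pos]
        col = col[col >= 0]
        freqs = np.bincount(col, minlength=4) / max(len(col), 1)
        f = freqs + pseudo
        f = f / f.sum()
        ic = 2.0 + float((f * np.log2(f)).sum())
        rows.append({"position": pos, "information_bits": ic,
                     "f_A": freqs[0], "f_C": freqs[1],
                     "f_G": freqs[2], "f_T": freqs[3]})
    return pd.DataFrame(rows)
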