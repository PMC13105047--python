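"""Mapping in-vitro RNA-binding k-mer preferences (RBNS R values) onto
positions around splice sites.

For each protein the concentration whose maximum k-mer enrichment is
largest is selected; positional k-mer fraction vectors (15-nt bins across
-75..+75) are then multiplied with the protein x k-mer matrix to give a
position x protein enrichment surface, compared between paired sequence
groups as log2 fold changes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topics import SiteSequence, encode, kmer_id_track, vocabulary

LOG2FC_FLOOR = 1e-9


@dataclass
class RBNSMatrix:
    R: pd.DataFrame                 # proteins x k-mers, all > 0
    chosen_concentration: pd.Series  # per protein
    k: int


def load_rbns(table: pd.DataFrame | str | os.PathLike) -> RBNSMatrix:
    """Assemble the protein x k-mer matrix from a long table with columns
    protein, concentration, kmer, R, keeping for each protein the
    concentration with the highest maximum enrichment."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t",
                            dtype={"concentration": str})
    required = {"protein", "concentration", "kmer", "R"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RBNS table missing columns {sorted(missing)}")
    klens = table["kmer"].str.len().unique()
    if len(klens) != 1:
        raise ValueError(f"mixed k-mer lengths in RBNS run: {sorted(klens)}")
    k = int(klens[0])
    vocab = vocabulary(k)
    rows = {}
    chosen = {}
    for prot, sub in table.groupby("protein"):
        best = sub.groupby("concentration")["R"].max().idxmax()
        sel = sub[sub["concentration"] == best].set_index("kmer")["R"]
        missing_kmers = set(vocab) - set(sel.index)
        if missing_kmers:
            raise ValueError(
                f"protein {prot}: {len(missing_kmers)} k-mers missing "
                f"(e.g. {sorted(missing_kmers)[:3]})")
        rows[prot] = sel.reindex(vocab).to_numpy()
        chosen[prot] = best
    R = pd.DataFrame(rows, index=vocab).T
    if (R <= 0).any().any():
        raise ValueError("RBNS R values must be positive")
    return RBNSMatrix(R=R, chosen_concentration=pd.Series(chosen), k=k)


@dataclass
class PositionEnrichment:
    bins: list[int]                           # bin start offsets
    fractions: dict[str, pd.DataFrame]        # group -> bins x k-mers
    enrichment: dict[str, pd.DataFrame]       # group -> bins x proteins
    log2fc: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def bin_kmer_fractions(site_sequences: list[SiteSequence], k: int,
                       bin_size: int = 15, span: int = 75) -> pd.DataFrame:
    """Per-bin k-mer fraction vectors over all sequences of a group.

    Sequences must cover offsets -span..span-1 (position 0 = splice-site
    base); a k-mer is assigned to the half-open 15-nt bin containing its
    start offset.  Each bin's fraction vector sums to 1; empty bins are
    NaN."""
    n_bins = 2 * span // bin_size
    vocab = vocabulary(k)
    counts = np.zeros((n_bins, len(vocab)), dtype=np.int64)
    for s in site_sequences:
        w0, w1 = s.window
        if w0 > -span or w1 < span - 1:
            raise ValueError(
                f"sequence window {s.window} does not cover -{span}..{span - 1}")
        ids = kmer_id_track(encode(s.sequence), k)
        for start_idx, kid in enumerate(ids):
            if kid < 0:
                continue
            off = w0 + start_idx
            if off < -span or off > span - k:
                continue
            counts[(off + span) // bin_size, kid] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / totals
    frac[totals[:, 0] == 0] = np.nan
    bins = [-span + b * bin_size for b in range(n_bins)]
    return pd.DataFrame(frac, index=bins, columns=vocab)


def position_enrichment(groups: dict[str, list[SiteSequence]],
                        rbns: RBNSMatrix,
                        pairs: list[tuple[str, str]] | None = None,
                        bin_size: int = 15,
                        span: int = 75) -> PositionEnrichment:
    """Position x protein enrichment surface per group: E[bin, protein] =
    sum_k f[bin, k] * R[protein, k], plus log2 fold changes for the
    requested (numerator, denominator) group pairs."""
    fractions, enrichment = {}, {}
    for name, seqs in groups.items():
        f = bin_kmer_fractions(seqs, rbns.k, bin_size, span)
        fractions[name] = f
        enrichment[name] = pd.DataFrame(
            f.to_numpy() @ rbns.R.to_numpy().T,
            index=f.index, columns=rbns.R.index)
    pe = PositionEnrichment(bins=list(next(iter(fractions.values())).index),
                            fractions=fractions, enrichment=enrichment)
    for (a, b) in pairs or []:
        ea, eb = enrichment[a], enrichment[b]
        pe.log2fc[(a, b)] = np.log2((ea + LOG2FC_FLOOR)
                                    / (eb + LOG2FC_FLOOR))
    return pe


def rank_proteins(pe: PositionEnrichment, top_n: int = 30) -> pd.DataFrame:
    """Proteins ranked by their highest absolute log2 fold change over all
    bins and group pairs (ties broken by protein name)."""
    if not pe.log2fc:
        raise ValueError("no log2fc tables computed")
    best = {}
    for table in pe.log2fc.values():
        m = table.abs().max(axis=0)
        for prot, val in m.items():
            if not np.isnan(val):
                best[prot] = max(best.get(prot, 0.0), float(val))
    df = (pd.DataFrame({"protein": list(best), "max_abs_log2fc":
                        [best[p] for p in best]})
          .sort_values(["max_abs_log2fc", "protein"],
                       ascending=[False, True], kind="mergesort")
          .reset_index(drop=True))
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n)
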