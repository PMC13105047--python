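"""Per-exon average CpG methylation and group comparisons.

The exon score is the *unweighted* mean of per-CpG percent methylation over
records inside the exon (coverage does not weight the mean).  Records on
the two strands of one CpG are averaged into a single site before scoring.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationRecord


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    index: int  # transcription-order exon index (0 = first exon)

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


def _collapse_strands(records: list[MethylationRecord]
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome, sorted CpG positions and percents.  A minus-strand
    record at position p+1 is folded onto the plus-strand cytosine at p and
    the two percents averaged when both are present."""
    by_site: dict[tuple[str, int], list[float]] = defaultdict(list)
    for r in records:
        pos = r.position if r.strand != "-" else r.position - 1
        by_site[(r.chrom, pos)].append(r.percent_methylated)
    per_chrom: dict[str, list[tuple[int, float]]] = defaultdict(list)
    for (chrom, pos), vals in by_site.items():
        per_chrom[chrom].append((pos, float(np.mean(vals))))
    out = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        pct = np.array([v for _, v in pairs])
        out[chrom] = (pos, pct)
    return out


def exon_methylation(exons: list[Exon],
                     records: list[MethylationRecord],
                     min_coverage: int = 1) -> pd.DataFrame:
    """Unweighted mean percent methylation per exon over covered CpGs.

    Exons with zero covered CpGs are excluded (their count is in the
    attrs of the returned frame)."""
    records = [r for r in records if r.coverage >= min_coverage]
    index = _collapse_strands(records)
    rows = []
    excluded = 0
    for ex in exons:
        if ex.chrom not in index:
            excluded += 1
            continue
        pos, pct = index[ex.chrom]
        lo = np.searchsorted(pos, ex.start, side="left")
        hi = np.searchsorted(pos, ex.end, side="right")
        if hi <= lo:
            excluded += 1
            continue
        rows.append({
            "exon_id": ex.exon_id, "gene_id": ex.gene_id,
            "transcript_id": ex.transcript_id, "exon_index": ex.index,
            "n_cpgs": int(hi - lo),
            "mean_percent": float(pct[lo:hi].mean()),
        })
    df = pd.DataFrame(rows, columns=["exon_id", "gene_id", "transcript_id",
                                     "exon_index", "n_cpgs", "mean_percent"])
    df.attrs["n_excluded_no_cpg"] = excluded
    return df


def compare_groups(exon_meth: pd.DataFrame, group_col: str = "group",
                   value_col: str = "mean_percent",
                   min_n: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups plus ECDF
    points per group.  Groups smaller than `min_n` are skipped with a
    note."""
    groups = {g: sub[value_col].to_numpy()
              for g, sub in exon_meth.groupby(group_col)}
    names = sorted(groups)
    test_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = groups[a], groups[b]
            if len(xa) < min_n or len(xb) < min_n:
                test_rows.append({"group_a": a, "group_b": b,
                                  "n_a": len(xa), "n_b": len(xb),
                                  "p_value": np.nan,
                                  "note": "group_below_min_n"})
                continue
            pooled = np.concatenate([xa, xb])
            if np.all(pooled == pooled[0]):
                p = 1.0  # complete ties carry no rank information
            else:
                p = float(stats.mannwhitneyu(
                    xa, xb, alternative="two-sided").pvalue)
            test_rows.append({"group_a": a, "group_b": b,
                              "n_a": len(xa), "n_b": len(xb),
                              "p_value": p, "note": ""})
    ecdf_rows = []
    for g in names:
        x = np.sort(groups[g])
        n = len(x)
        for i, v in enumerate(x, start=1):
            ecdf_rows.append({"group": g, "value": float(v), "ecdf": i / n})
    return pd.DataFrame(test_rows), pd.DataFrame(ecdf_rows)
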