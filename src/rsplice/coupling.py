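"""Association between first-intron and downstream-intron recursive
splicing within transcripts."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import ClassifiedIntron, RS_CLASSES


@dataclass
class TranscriptRSStatus:
    transcript_id: str
    gene_id: str
    n_detected_introns: int
    first_status: str      # 'RS' | 'noRS' | 'unknown'
    downstream_status: str  # 'RS' | 'noRS'
    downstream_rs_fraction: float


def transcript_status(classified: list[ClassifiedIntron],
                      min_introns: int = 3) -> list[TranscriptRSStatus]:
    """Per-transcript recursive-splicing status.

    The first intron is 'RS' if it carries any RS-class junction, 'noRS' if
    it carries only exact-junction (basic) evidence, and 'unknown' if it was
    not detected at all.  Downstream status is 'RS' iff any non-first intron
    has RS evidence.  `min_introns` only marks inclusion in the association
    test; all transcripts are reported.
    """
    per_tx: dict[str, list[ClassifiedIntron]] = defaultdict(list)
    for ci in classified:
        per_tx[ci.intron.transcript_id].append(ci)
    out = []
    for tid in sorted(per_tx):
        cis = per_tx[tid]
        detected_keys = {ci.intron.key for ci in cis}
        first_classes = {ci.rs_class for ci in cis
                         if ci.intron.position_class == "first"}
        if any(c in RS_CLASSES for c in first_classes):
            first = "RS"
        elif "basic" in first_classes:
            first = "noRS"
        else:
            first = "unknown"
        down = [ci for ci in cis if ci.intron.position_class != "first"]
        down_keys = {ci.intron.key for ci in down}
        down_rs_keys = {ci.intron.key for ci in down
                        if ci.rs_class in RS_CLASSES}
        out.append(TranscriptRSStatus(
            transcript_id=tid, gene_id=cis[0].intron.gene_id,
            n_detected_introns=len(detected_keys),
            first_status=first,
            downstream_status="RS" if down_rs_keys else "noRS",
            downstream_rs_fraction=(len(down_rs_keys) / len(down_keys)
                                    if down_keys else 0.0)))
    return out


def status_table(statuses: list[TranscriptRSStatus]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in statuses])


def first_downstream_fisher(statuses: list[TranscriptRSStatus],
                            min_introns: int = 3,
                            method: str = "sample") -> dict:
    """Fisher's exact test of first-intron RS x downstream RS over
    transcripts with known first status and >= `min_introns` detected
    introns.

    The reported odds ratio is the sample (cross-product) estimate with a
    Haldane 0.5 correction when any cell is zero; `method='conditional'`
    switches to the conditional maximum-likelihood estimate.
    """
    use = [s for s in statuses
           if s.first_status != "unknown"
           and s.n_detected_introns >= min_introns]
    a = sum(1 for s in use
            if s.first_status == "RS" and s.downstream_status == "RS")
    b = sum(1 for s in use
            if s.first_status == "RS" and s.downstream_status == "noRS")
    c = sum(1 for s in use
            if s.first_status == "noRS" and s.downstream_status == "RS")
    d = sum(1 for s in use
            if s.first_status == "noRS" and s.downstream_status == "noRS")
    table = np.array([[a, b], [c, d]])
    corrected = (table == 0).any()
    if method == "conditional":
        odds = float(stats.contingency.odds_ratio(
            table, kind="conditional").statistic)
    else:
        t = table + 0.5 if corrected else table
        odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"contingency": table, "odds_ratio": odds, "p_value": p,
            "n_transcripts": len(use), "zero_cell_corrected": bool(corrected)}
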