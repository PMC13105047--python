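"""Summaries of targeted-validation (LSV-seq) junction counts against
classifier predictions.

The module consumes a per-intron junction-count table (the boundary after
upstream read processing): intron_id, group, predicted_rs, rs_read_count,
total_reads.  Precision/recall follow the convention of treating the
classifier output as truth and the targeted assay as the observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["intron_id", "group", "predicted_rs", "rs_read_count"]

# named read-threshold presets for the detection/PR summaries
THRESHOLD_PRESETS = {"any": 1, "gt2": 3, "ge10": 10}


def _check(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"validation table missing columns {missing}")
    if (records["rs_read_count"] < 0).any():
        raise ValueError("negative read counts")
    return records


def group_detection_rates(records: pd.DataFrame,
                          min_reads: int = 1) -> pd.DataFrame:
    """Per group: introns tested, introns with >= min_reads recursive-
    junction reads, and the detection percentage (2 decimals)."""
    records = _check(records)
    rows = []
    for group, sub in records.groupby("group"):
        tested = len(sub)
        detected = int((sub["rs_read_count"] >= min_reads).sum())
        rows.append({
            "group": group, "tested": tested, "detected": detected,
            "percent": (round(100.0 * detected / tested, 2)
                        if tested else np.nan),
        })
    return pd.DataFrame(rows)


def precision_recall_vs_threshold(records: pd.DataFrame,
                                  thresholds: list[int]) -> pd.DataFrame:
    """Precision and recall of the targeted assay at each read threshold,
    with classifier predictions as the reference labels.

    observed positive = rs_read_count >= t; TP = predicted & observed,
    FP = not-predicted & observed, FN = predicted & not-observed."""
    records = _check(records)
    pred = records["predicted_rs"].astype(bool).to_numpy()
    reads = records["rs_read_count"].to_numpy()
    rows = []
    for t in thresholds:
        obs = reads >= t
        tp = int((pred & obs).sum())
        fp = int((~pred & obs).sum())
        fn = int((pred & ~obs).sum())
        tn = int((~pred & ~obs).sum())
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / (tp + fn) if (tp + fn) else np.nan
        rows.append({"threshold": t, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     "precision": precision, "recall": recall})
    return pd.DataFrame(rows)
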