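"""Per-intron feature assembly and random-forest recursive-splicing
classifiers.

Features per intron: grade-of-membership topic expectations for four
regions (upstream exon, first 50 intron bases after the 5'SS, last 50
before the 3'SS, downstream exon), log10 intron length, log10 gene TPM and
upstream-exon mean CpG methylation.  For downstream introns the gene's
first-intron feature block is appended.  Labels come from junction
evidence: 'RS' needs a recursive-class junction, 'basic' needs exact
canonical-junction evidence (introns without junction support carry no
label and are excluded from training).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (precision_recall_curve, roc_auc_score,
                             roc_curve)
from sklearn.model_selection import train_test_split

from .io import Genome, GenomeAnnotation
from .junctions import ClassifiedIntron, Intron, RS_CLASSES
from .topics import TopicModel, KmerCountMatrix, fit_mixture, \
    per_sequence_kmer_counts, topic_expectations, vocabulary

REGIONS = ("upstream_exon", "ss5_intron", "ss3_intron", "downstream_exon")

HYPERPARAMS = {
    # n_estimators, min_samples_split, min_samples_leaf, max_depth
    "first": (100, 10, 5, 3),
    "downstream": (100, 10, 5, 2),
}


def intron_id(intron: Intron) -> str:
    return f"{intron.chrom}:{intron.start}-{intron.end}:{intron.strand}"


def _exon_id(chrom, start, end, strand) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def _flanking_exons(ann: GenomeAnnotation, intron: Intron):
    rec = ann.transcripts.get(intron.transcript_id)
    if rec is None:
        return None
    for (s1, e1), (s2, e2) in zip(rec.exons, rec.exons[1:]):
        if e1 + 1 == intron.start and s2 - 1 == intron.end:
            if intron.strand == "+":
                return (s1, e1), (s2, e2)
            return (s2, e2), (s1, e1)
    return None


def region_sequences(intron: Intron, ann: GenomeAnnotation, genome: Genome,
                     exon_truncate: int = 300) -> dict[str, str] | None:
    """Sense-strand sequences of the four feature regions; exons are
    truncated to `exon_truncate` nt at the splice-site-proximal end."""
    flanks = _flanking_exons(ann, intron)
    if flanks is None or intron.length < 100:
        return None
    (u_s, u_e), (d_s, d_e) = flanks
    chrom, strand = intron.chrom, intron.strand
    up = genome.fetch(chrom, u_s, u_e, strand)[-exon_truncate:]
    down = genome.fetch(chrom, d_s, d_e, strand)[:exon_truncate]
    intron_seq = genome.fetch(chrom, intron.start, intron.end, strand)
    return {
        "upstream_exon": up,
        "ss5_intron": intron_seq[:50],
        "ss3_intron": intron_seq[-50:],
        "downstream_exon": down,
    }


def fit_region_models(introns: list[Intron], ann: GenomeAnnotation,
                      genome: Genome, k: int = 4, n_topics: int = 6,
                      seed: int = 0,
                      max_iter: int = 50) -> dict[str, TopicModel]:
    """Fit one LDA mixture per feature region on per-intron k-mer counts."""
    seqs: dict[str, list[str]] = {r: [] for r in REGIONS}
    for intr in introns:
        regions = region_sequences(intr, ann, genome)
        if regions is None:
            continue
        for r in REGIONS:
            seqs[r].append(regions[r])
    models = {}
    for i, r in enumerate(REGIONS):
        counts = per_sequence_kmer_counts(seqs[r], k)
        counts = counts[counts.sum(axis=1) > 0]
        meta = pd.DataFrame({"doc": np.arange(len(counts))})
        matrix = KmerCountMatrix(counts, vocabulary(k), meta, k)
        models[r] = fit_mixture(matrix, n_topics=n_topics, seed=seed + i,
                                max_iter=max_iter)
    return models


def feature_block(introns: list[Intron], ann: GenomeAnnotation,
                  genome: Genome, models: dict[str, TopicModel],
                  k: int = 4) -> pd.DataFrame:
    """Topic-expectation features plus log10 length for a set of introns,
    indexed by intron id.  Rows with a missing or degenerate region are
    dropped."""
    rows, ids = [], []
    region_seqs: dict[str, list[str]] = {r: [] for r in REGIONS}
    kept: list[Intron] = []
    for intr in introns:
        regions = region_sequences(intr, ann, genome)
        if regions is None:
            continue
        kept.append(intr)
        for r in REGIONS:
            region_seqs[r].append(regions[r])
    if not kept:
        return pd.DataFrame()
    blocks = []
    for r in REGIONS:
        counts = per_sequence_kmer_counts(region_seqs[r], k)
        ok = counts.sum(axis=1) > 0
        mem = np.full((len(kept), models[r].n_topics), np.nan)
        if ok.any():
            mem[ok] = topic_expectations(models[r], counts[ok]).to_numpy()
        blocks.append(pd.DataFrame(
            mem, columns=[f"{r}_topic{t + 1}"
                          for t in range(models[r].n_topics)]))
    df = pd.concat(blocks, axis=1)
    df.index = [intron_id(i) for i in kept]
    df["log10_length"] = [np.log10(i.length) for i in kept]
    return df.dropna()


def intron_labels(classified: list[ClassifiedIntron]) -> pd.Series:
    """'RS' if any recursive-class record, else 'basic' for exact-evidence
    introns."""
    status: dict[str, str] = {}
    for ci in classified:
        iid = intron_id(ci.intron)
        if ci.rs_class in RS_CLASSES:
            status[iid] = "RS"
        else:
            status.setdefault(iid, "basic")
    return pd.Series(status, name="label")


def build_features(classified: list[ClassifiedIntron],
                   introns: list[Intron],
                   ann: GenomeAnnotation, genome: Genome,
                   gene_tpm: pd.Series, exon_meth: pd.DataFrame,
                   scope: str,
                   models: dict[str, TopicModel],
                   first_models: dict[str, TopicModel] | None = None,
                   min_tpm: float = 1.0) -> pd.DataFrame:
    """Labelled feature table for one classifier scope.

    `introns` is the constitutive-intron universe; only labelled introns
    from genes with TPM >= `min_tpm` and complete features survive.  For
    scope='downstream', `first_models` (defaults to `models`) scores the
    gene's first-intron block, appended with a ``first_`` prefix.
    """
    if scope not in ("first", "downstream"):
        raise ValueError("scope must be 'first' or 'downstream'")
    labels = intron_labels(classified)
    meth_by_exon = exon_meth.set_index("exon_id")["mean_percent"]

    if scope == "first":
        pool = [i for i in introns if i.position_class == "first"]
    else:
        pool = [i for i in introns if i.position_class != "first"]
    by_id = {intron_id(i): i for i in pool}
    feats = feature_block(pool, ann, genome, models)
    feats = feats[feats.index.isin(labels.index)]

    rows = []
    for iid, frow in feats.iterrows():
        intr = by_id[iid]
        tpm = gene_tpm.get(intr.gene_id, 0.0)
        if tpm < min_tpm:
            continue
        flanks = _flanking_exons(ann, intr)
        up_id = _exon_id(intr.chrom, *flanks[0], intr.strand)
        meth = meth_by_exon.get(up_id, np.nan)
        if np.isnan(meth):
            continue
        row = dict(frow)
        row.update(intron_id=iid, gene_id=intr.gene_id,
                   log10_tpm=np.log10(tpm), upstream_exon_methylation=meth,
                   label=labels[iid])
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.set_index("intron_id")

    if scope == "downstream":
        fmods = first_models or models
        first_pool = [i for i in introns if i.position_class == "first"]
        fblock = feature_block(first_pool, ann, genome, fmods)
        gene_of = {intron_id(i): i.gene_id for i in first_pool}
        fblock["gene_id"] = [gene_of[iid] for iid in fblock.index]
        fblock = fblock.groupby("gene_id").first()
        fblock.columns = [f"first_{c}" for c in fblock.columns]
        df = df.join(fblock, on="gene_id", how="inner")
    return df


# ---------------------------------------------------------------------------
# training / evaluation


@dataclass
class ClassifierReport:
    auc: float
    roc: pd.DataFrame
    pr: pd.DataFrame
    importances: pd.Series
    scope: str
    seed: int
    hyperparameters: dict
    feature_names: list[str]
    model: RandomForestClassifier = field(repr=False)
    n_train: int = 0
    n_test: int = 0


def _feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    drop = {"label", "gene_id"}
    cols = [c for c in features.columns
            if c not in drop and pd.api.types.is_numeric_dtype(features[c])]
    X = features[cols].to_numpy(dtype=float)
    y = (features["label"] == "RS").to_numpy()
    return X, y, cols


def train_evaluate(features: pd.DataFrame, scope: str, seed: int = 0,
                   stratify: bool = True) -> ClassifierReport:
    """Random forest with the scope's fixed hyperparameters, evaluated on a
    held-out third of the data."""
    X, y, cols = _feature_matrix(features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    n_est, min_split, min_leaf, max_depth = HYPERPARAMS[scope]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=1 / 3, random_state=seed,
        stratify=y if stratify else None)
    rf = RandomForestClassifier(
        n_estimators=n_est, min_samples_split=min_split,
        min_samples_leaf=min_leaf, max_depth=max_depth,
        random_state=seed)
    rf.fit(X_tr, y_tr)
    prob = rf.predict_proba(X_te)[:, 1]
    auc = float(roc_auc_score(y_te, prob))
    fpr, tpr, roc_thr = roc_curve(y_te, prob)
    prec, rec, pr_thr = precision_recall_curve(y_te, prob)
    return ClassifierReport(
        auc=auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr,
                          "threshold": roc_thr}),
        pr=pd.DataFrame({"precision": prec, "recall": rec,
                         "threshold": np.append(pr_thr, np.nan)}),
        importances=pd.Series(rf.feature_importances_, index=cols)
        .sort_values(ascending=False),
        scope=scope, seed=seed,
        hyperparameters={"n_estimators": n_est,
                         "min_samples_split": min_split,
                         "min_samples_leaf": min_leaf,
                         "max_depth": max_depth},
        feature_names=cols, model=rf,
        n_train=len(y_tr), n_test=len(y_te))


def matched_subsets(features: pd.DataFrame,
                    match_on: tuple[str, ...] = ("log10_length", "log10_tpm"),
                    caliper: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Greedy 1-nearest-neighbour matching without replacement on the
    standardized `match_on` covariates within `caliper`; returns the
    balanced subset of rows."""
    rng = np.random.default_rng(seed)
    y = features["label"] == "RS"
    Z = features[list(match_on)].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    minority = "RS" if y.sum() <= (~y).sum() else "basic"
    min_idx = np.flatnonzero(features["label"] == minority)
    maj_idx = np.flatnonzero(features["label"] != minority)
    available = np.ones(len(maj_idx), dtype=bool)
    picked = []
    for i in rng.permutation(min_idx):
        d = np.linalg.norm(Z[maj_idx] - Z[i], axis=1)
        d[~available] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper:
            available[j] = False
            picked.append((i, maj_idx[j]))
    if not picked:
        raise ValueError("no matches within caliper")
    keep = sorted({i for pair in picked for i in pair})
    return features.iloc[keep]


def score(features: pd.DataFrame, report: ClassifierReport) -> pd.Series:
    """RS probability per intron from a trained model (schema-checked)."""
    missing = [c for c in report.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch: missing {missing}")
    X = features[report.feature_names].to_numpy(dtype=float)
    prob = report.model.predict_proba(X)[:, 1]
    return pd.Series(prob, index=features.index, name="rs_probability")
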