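"""End-to-end orchestration of the recursive-splicing analysis.

``run_all`` executes the stages in dependency order (classify ->
topics/profiles/methyl -> coupling -> train -> rbns -> validate), writes
every stage output as a TSV with a fixed float format, and emits a manifest
with per-output row counts and checksums so that seeded runs can be
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import coupling as cpl
from . import io as rio
from . import junctions as jn
from . import lsvseq as lsv
from . import methyl as mt
from . import profiles as pf
from . import rbns as rb
from . import synthetic as syn
from . import topics as tp

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineParams:
    seed: int = 0
    min_reads: int = 3
    min_rs_distance: int = 75
    min_rs_intron_length: int = 150
    min_basic_length: int = 75
    k: int = 4
    n_topics: int = 6
    group_size: int = 15
    window_smooth: int = 6
    min_tpm: float = 1.0
    metagene_bins: int = 50
    rbns_span: int = 75
    rbns_bin: int = 15
    max_model_introns: int = 800   # cap for region-model fitting
    lda_max_iter: int = 30         # batch VB iterations for pipeline fits


@dataclass
class PipelineInputs:
    ann: rio.GenomeAnnotation
    genome: rio.Genome
    nascent: list[rio.SpliceJunction]
    mature: list[rio.SpliceJunction]
    tpm: pd.DataFrame
    meth_records: list[rio.MethylationRecord]
    rbns_table: pd.DataFrame | None = None


def load_bundle_dir(path: str | Path) -> PipelineInputs:
    """Load a bundle-layout directory (the layout `simulate` writes)."""
    path = Path(path)
    nascent, mature = [], []
    for i, p in enumerate(sorted(path.glob("nascent_*.SJ.out.tab"))):
        nascent.extend(rio.read_sj_table(p, "nascent", f"nascent_{i + 1}"))
    for i, p in enumerate(sorted(path.glob("mature_*.SJ.out.tab"))):
        mature.extend(rio.read_sj_table(p, "mature", f"mature_{i + 1}"))
    rbns_path = path / "rbns.tsv"
    return PipelineInputs(
        ann=rio.read_gtf(path / "annotation.gtf"),
        genome=rio.Genome(path / "genome.fa"),
        nascent=nascent, mature=mature,
        tpm=rio.read_tpm(path / "expression.tsv"),
        meth_records=rio.read_bedmethyl(path / "methylation.bed"),
        rbns_table=(pd.read_csv(rbns_path, sep="\t",
                                dtype={"concentration": str})
                    if rbns_path.exists() else None))


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# stages


def stage_classify(inputs: PipelineInputs, params: PipelineParams):
    introns = jn.extract_constitutive_introns(inputs.ann)
    classified, log = jn.classify_junctions(
        introns, inputs.nascent, inputs.mature,
        min_unique_reads=params.min_reads,
        min_rs_distance=params.min_rs_distance,
        min_rs_intron_length=params.min_rs_intron_length,
        min_basic_length=params.min_basic_length)
    return introns, classified, log


def classified_table(classified: list[jn.ClassifiedIntron]) -> pd.DataFrame:
    rows = []
    for ci in classified:
        i = ci.intron
        rows.append({
            "intron_id": clf.intron_id(i), "chrom": i.chrom,
            "start": i.start, "end": i.end, "strand": i.strand,
            "gene_id": i.gene_id, "transcript_id": i.transcript_id,
            "position_class": i.position_class, "length": i.length,
            "rs_class": ci.rs_class,
            "recursive_5ss": ci.recursive_5ss if ci.recursive_5ss else "",
            "recursive_3ss": ci.recursive_3ss if ci.recursive_3ss else "",
            "n_junctions": len(ci.supporting_junctions),
            "total_reads": sum(j.unique_reads
                               for j in ci.supporting_junctions),
        })
    return pd.DataFrame(rows)


def stage_topics(classified, genome, params: PipelineParams):
    first = [ci for ci in classified
             if ci.intron.position_class == "first"]
    seqs = tp.extract_site_sequences(first, genome, "canonical5",
                                     window=(-50, 50))
    matrix = tp.grouped_kmer_matrix(seqs, group_size=params.group_size,
                                    k=params.k, seed=params.seed)
    model = tp.fit_mixture(matrix, n_topics=params.n_topics,
                           seed=params.seed, max_iter=params.lda_max_iter)
    probs = model.topic_kmer_probs.reset_index(names="topic") \
        .melt(id_vars="topic", var_name="kmer", value_name="probability")
    mem = pd.concat([model.meta.reset_index(drop=True),
                     model.doc_topic_memberships], axis=1)
    driving = tp.driving_kmers(model)
    # positional design: documents are smoothed offsets relative to the
    # splice site (structure-plot-ready long format)
    pos_seqs = tp.extract_site_sequences(first, genome, "canonical5",
                                         window=(-30, 50))
    pos_matrix = tp.positional_kmer_matrix(
        pos_seqs, k=params.k, window_smooth=params.window_smooth)
    pos_model = tp.fit_mixture(pos_matrix, n_topics=params.n_topics,
                               seed=params.seed,
                               max_iter=params.lda_max_iter)
    pos_mem = pd.concat([pos_model.meta.reset_index(drop=True),
                         pos_model.doc_topic_memberships], axis=1)
    return model, {"topic_kmer_probs": probs, "memberships": mem,
                   "driving_kmers": driving,
                   "positional_memberships": pos_mem}


def stage_profiles(classified, ann, genome, params: PipelineParams):
    first = [ci for ci in classified if ci.intron.position_class == "first"]
    metagene = pf.metagene_gc(first, ann, genome, bins=params.metagene_bins)
    seqs = tp.extract_site_sequences(first, genome, "canonical5",
                                     window=(-50, 100))
    wgc = pf.window_gc(seqs)
    rs_seq = [s.sequence for s in seqs if s.rs_class in jn.RS_CLASSES]
    basic_seq = [s.sequence for s in seqs if s.rs_class == "basic"]
    volcano = (pf.tetramer_enrichment(rs_seq, basic_seq, k=params.k)
               if rs_seq and basic_seq else pd.DataFrame())
    narrow = tp.extract_site_sequences(first, genome, "canonical5",
                                       window=(-3, 6))
    pwm = (pf.pwm_information([s.sequence for s in narrow])
           if narrow else pd.DataFrame())
    return {"metagene_gc": metagene, "window_gc": wgc,
            "tetramer_volcano": volcano, "pwm_ic": pwm}


def all_exons(ann: rio.GenomeAnnotation) -> list[mt.Exon]:
    out = []
    for tid, rec in sorted(ann.transcripts.items()):
        exons = rec.exons if rec.strand == "+" else rec.exons[::-1]
        for idx, (s, e) in enumerate(exons):
            out.append(mt.Exon(rec.chrom, s, e, rec.strand, rec.gene_id,
                               tid, idx))
    return out


def stage_methyl(inputs: PipelineInputs, classified, params: PipelineParams):
    exons = all_exons(inputs.ann)
    meth = mt.exon_methylation(exons, inputs.meth_records)
    labels = clf.intron_labels(classified)
    first_status = {}
    for ci in classified:
        if ci.intron.position_class == "first":
            iid = clf.intron_id(ci.intron)
            first_status[ci.intron.gene_id] = labels[iid]
    def group(row):
        if row["exon_index"] != 0:
            return "other"
        status = first_status.get(row["gene_id"])
        if status == "RS":
            return "first_RS"
        if status == "basic":
            return "first_noRS"
        return "first_unknown"
    if len(meth):
        meth = meth.assign(group=meth.apply(group, axis=1))
        tests, ecdf = mt.compare_groups(
            meth[meth["group"].isin(["first_RS", "first_noRS"])])
    else:
        tests, ecdf = pd.DataFrame(), pd.DataFrame()
    return meth, {"exon_methylation": meth, "methylation_tests": tests,
                  "methylation_ecdf": ecdf}


def stage_coupling(classified, params: PipelineParams):
    statuses = cpl.transcript_status(classified)
    fisher = cpl.first_downstream_fisher(statuses)
    table = cpl.status_table(statuses)
    ct = fisher["contingency"]
    test_df = pd.DataFrame([{
        "n_transcripts": fisher["n_transcripts"],
        "first_RS_down_RS": ct[0, 0], "first_RS_down_noRS": ct[0, 1],
        "first_noRS_down_RS": ct[1, 0], "first_noRS_down_noRS": ct[1, 1],
        "odds_ratio": fisher["odds_ratio"], "p_value": fisher["p_value"],
        "zero_cell_corrected": fisher["zero_cell_corrected"],
    }])
    return statuses, {"transcript_status": table, "coupling_test": test_df}


def stage_train(inputs: PipelineInputs, introns, classified, meth,
                params: PipelineParams, scope: str = "first"):
    gene_tpm = rio.gene_tpm(inputs.tpm)
    meth = meth.rename(columns={"exon_id": "exon_id"})
    pool = [i for i in introns
            if (i.position_class == "first") == (scope == "first")]
    rng = np.random.default_rng(params.seed)
    if len(pool) > params.max_model_introns:
        idx = rng.choice(len(pool), params.max_model_introns, replace=False)
        model_pool = [pool[i] for i in sorted(idx)]
    else:
        model_pool = pool
    models = clf.fit_region_models(model_pool, inputs.ann, inputs.genome,
                                   k=params.k, n_topics=params.n_topics,
                                   seed=params.seed,
                                   max_iter=params.lda_max_iter)
    first_models = models
    if scope == "downstream":
        fpool = [i for i in introns if i.position_class == "first"]
        first_models = clf.fit_region_models(
            fpool[:params.max_model_introns], inputs.ann, inputs.genome,
            k=params.k, n_topics=params.n_topics, seed=params.seed + 100,
            max_iter=params.lda_max_iter)
    features = clf.build_features(
        classified, introns, inputs.ann, inputs.genome, gene_tpm, meth,
        scope, models, first_models=first_models, min_tpm=params.min_tpm)
    if features.empty or features["label"].nunique() < 2:
        return None, None, features
    report = clf.train_evaluate(features, scope, seed=params.seed)
    scores = clf.score(features, report)
    return report, scores, features


def stage_rbns(inputs: PipelineInputs, classified, params: PipelineParams):
    if inputs.rbns_table is None:
        return None, {}
    matrix = rb.load_rbns(inputs.rbns_table)
    span = params.rbns_span
    window = (-span, span - 1)
    first = [ci for ci in classified if ci.intron.position_class == "first"]
    rs_first = [ci for ci in first if ci.rs_class in jn.RS_CLASSES]
    basic_first = [ci for ci in first if ci.rs_class == "basic"]
    groups = {
        "canonical5_RS": tp.extract_site_sequences(
            rs_first, inputs.genome, "canonical5", window),
        "canonical5_basic": tp.extract_site_sequences(
            basic_first, inputs.genome, "canonical5", window),
        "recursive5_RS": tp.extract_site_sequences(
            [ci for ci in rs_first if ci.recursive_5ss is not None],
            inputs.genome, "recursive5", window),
    }
    groups = {k: v for k, v in groups.items() if v}
    pairs = []
    if "canonical5_RS" in groups and "canonical5_basic" in groups:
        pairs.append(("canonical5_RS", "canonical5_basic"))
    if "recursive5_RS" in groups and "canonical5_RS" in groups:
        pairs.append(("recursive5_RS", "canonical5_RS"))
    pe = rb.position_enrichment(groups, matrix, pairs=pairs,
                                bin_size=params.rbns_bin, span=span)
    e_long = pd.concat([
        e.reset_index(names="bin").melt(id_vars="bin", var_name="protein",
                                        value_name="R")
        .assign(group=name)
        for name, e in pe.enrichment.items()])
    fc_long = pd.concat([
        t.reset_index(names="bin").melt(id_vars="bin", var_name="protein",
                                        value_name="log2fc")
        .assign(pair=f"{a}_vs_{b}")
        for (a, b), t in pe.log2fc.items()]) if pe.log2fc else pd.DataFrame()
    top = rb.rank_proteins(pe) if pe.log2fc else pd.DataFrame()
    return pe, {"position_protein_R": e_long, "log2fc": fc_long,
                "top_proteins": top}


def stage_validate(classified, scores: pd.Series | None,
                   params: PipelineParams):
    """Build a synthetic validation table from classifier scores and the
    nascent recursive-junction read support, then summarize it.

    Quadrant groups: 1 = predicted RS with RNA-seq RS evidence, 2 = neither,
    3 = predicted only, 4 = evidence only."""
    if scores is None:
        return {}
    rs_reads = {}
    for ci in classified:
        if ci.rs_class in jn.RS_CLASSES:
            iid = clf.intron_id(ci.intron)
            rs_reads[iid] = rs_reads.get(iid, 0) + sum(
                j.unique_reads for j in ci.supporting_junctions)
    rows = []
    for iid, prob in scores.items():
        pred = prob >= 0.5
        reads = rs_reads.get(iid, 0)
        group = 1 if (pred and reads) else 2 if (not pred and not reads) \
            else 3 if pred else 4
        rows.append({"intron_id": iid, "group": group,
                     "predicted_rs": int(pred), "rs_read_count": reads,
                     "total_reads": reads})
    records = pd.DataFrame(rows)
    rates = lsv.group_detection_rates(records)
    pr = lsv.precision_recall_vs_threshold(records, [1, 3, 5, 10])
    return {"validation_records": records, "group_rates": rates,
            "pr_by_threshold": pr}


# ---------------------------------------------------------------------------
# run-all


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(inputs: PipelineInputs, outdir: str | Path,
            params: PipelineParams | None = None) -> dict:
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, pd.DataFrame] = {}

    introns, classified, log = stage_classify(inputs, params)
    written["introns_classified"] = classified_table(classified)
    written["junctions_discarded"] = log
    written["junction_length_summary"] = jn.junction_length_summary(classified)
    written["rs_site_motifs"] = jn.motif_at_recursive_sites(
        classified, inputs.genome)

    _, topic_out = stage_topics(classified, inputs.genome, params)
    written.update(topic_out)

    written.update(stage_profiles(classified, inputs.ann, inputs.genome,
                                  params))

    meth, meth_out = stage_methyl(inputs, classified, params)
    written.update(meth_out)

    _, coupling_out = stage_coupling(classified, params)
    written.update(coupling_out)

    report, scores, features = stage_train(inputs, introns, classified,
                                           meth, params, scope="first")
    if report is not None:
        written["classifier_report"] = pd.DataFrame([{
            "scope": report.scope, "auc": report.auc,
            "n_train": report.n_train, "n_test": report.n_test,
            **{f"hp_{k}": v for k, v in report.hyperparameters.items()}}])
        written["roc"] = report.roc
        written["pr"] = report.pr
        written["importances"] = (report.importances.rename("importance")
                                  .rename_axis("feature").reset_index())
        written["scores"] = scores.rename_axis("intron_id").reset_index()

    _, rbns_out = stage_rbns(inputs, classified, params)
    written.update(rbns_out)

    written.update(stage_validate(classified, scores, params))

    manifest = {"params": vars(params), "outputs": {}}
    for name in sorted(written):
        df = written[name]
        path = outdir / f"{name}.tsv"
        write_tsv(df, path)
        manifest["outputs"][name] = {"rows": int(len(df)),
                                     "sha256": _sha256(path)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_all_synthetic(outdir: str | Path, seed: int = 0,
                      n_genes: int = 200,
                      synthetic_config: syn.SyntheticConfig | None = None,
                      params: PipelineParams | None = None) -> dict:
    """Generate a synthetic bundle and run the full pipeline on it."""
    outdir = Path(outdir)
    cfg = synthetic_config or syn.SyntheticConfig(
        seed=seed, n_genes=n_genes, read_floor=3)
    bundle = syn.generate(cfg, outdir / "bundle")
    inputs = load_bundle_dir(bundle.outdir)
    params = params or PipelineParams(seed=seed)
    return run_all(inputs, outdir / "results", params)
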