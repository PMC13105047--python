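# rsplice

Detection and sequence analysis of **recursive splicing (RS)** — the
stepwise removal of long introns in multiple segments through internal,
regenerated "AGGU ratchet point" splice sites — from nascent-RNA
splice-junction tables.

The package is aimed at computational RNA biologists who have STAR
`SJ.out.tab` junction tables from nascent (e.g. DRB-washout) and mature
RNA-seq of the same cells, a genome and a GTF annotation, and want to

1. **classify** constitutive introns into four junction classes — `basic`
   (both boundaries annotated), `RS5` (recursive 5'SS inside the intron),
   `RS3` (recursive 3'SS inside) and `nested` (both recursive) — using
   nascent-unique junctions with ≥ 3 unique reads, recursive sites ≥ 75 nt
   from the annotated sites, host introns ≥ 150 nt;
2. **discover sequence features** around splice sites with latent Dirichlet
   allocation (LDA) on positional or grouped tetramer counts: documents
   $d$ with counts $x_{dw}$ are modelled with topic–k-mer probabilities
   $\beta_{tw}$ ($\sum_w \beta_{tw}=1$) and grade-of-membership vectors
   $\theta_{dt}$ ($\sum_t \theta_{dt}=1$); topics are ranked by the
   Poisson-KL driving-k-mer score
   $s_{tw} = \beta_{tw}\ln(\beta_{tw}/q_w) + q_w - \beta_{tw}$, with $q_w$
   the mean probability of $w$ in the other topics;
3. **quantify CpG methylation** per exon (unweighted mean percent over
   covered CpGs) and compare RS vs non-RS first exons by Wilcoxon rank-sum;
4. **test the first↔downstream coupling**: a Fisher's exact test of
   first-intron RS against downstream-intron RS over transcripts with ≥ 3
   detected introns, reporting the sample (cross-product) odds ratio;
5. **predict RS** with random-forest classifiers over per-intron features
   (4 × 6 topic expectations, log10 intron length, log10 gene TPM, upstream
   exon methylation; downstream introns additionally carry their gene's
   first-intron block);
6. **rank candidate RNA-binding proteins** by mapping in-vitro RBNS k-mer
   enrichments (R values) onto splice-site positions via
   $E_{bp} = \sum_w f_{bw} R_{pw}$ (15-nt bins across ±75 nt) and comparing
   paired groups as log2 fold changes;
7. **summarize targeted validation** (LSV-seq-style junction-count tables)
   as per-group detection rates and precision/recall against classifier
   predictions.

A fully seeded synthetic-data generator (`rsplice.synthetic`) emulates all
required inputs with planted signal — CG-rich motifs at RS first-intron
5'SS, purine-diluted pyrimidine tracts, AGGU recursive sites, a tunable
first↔downstream odds ratio, methylation and length shifts — so the entire
pipeline is testable without any download.

## Worked example

```python
from rsplice import io, junctions, coupling
from rsplice.synthetic import SyntheticConfig, generate

bundle = generate(SyntheticConfig(seed=1, n_genes=500, read_floor=3),
                  "demo_bundle")
ann = io.read_gtf(bundle.gtf)
nascent = [j for i, p in enumerate(bundle.nascent_sj)
           for j in io.read_sj_table(p, "nascent", f"n{i}")]
mature = [j for i, p in enumerate(bundle.mature_sj)
          for j in io.read_sj_table(p, "mature", f"m{i}")]

introns = junctions.extract_constitutive_introns(ann)
classified, _ = junctions.classify_junctions(introns, nascent, mature)
res = coupling.first_downstream_fisher(
    coupling.transcript_status(classified))
print(len(introns), res["odds_ratio"], res["p_value"])
```

This prints `1976` constitutive introns, classified as 1656 basic, 153
RS5, 97 RS3 and 70 nested records, and recovers the planted coupling
(generated at odds ratio 2.2) as `OR = 2.178` with `p = 1.3e-4` over the
500 transcripts.  The junction-length summary shows what the classes mean
structurally: recursive junctions come from much longer host introns
(mean RS5 junction length 1001 nt vs 552 nt for basic) and are strongly
enriched in first introns (51–56 % first-intron fraction vs 20 % for
basic).

The same analysis end to end, from the command line:

```bash
rsplice run-all --synthetic --seed 7 --n-genes 200 --outdir demo
```

writes every stage table (`introns_classified.tsv`, `memberships.tsv`,
`driving_kmers.tsv`, `metagene_gc.tsv`, `exon_methylation.tsv`,
`coupling_test.tsv`, `roc.tsv`, `importances.tsv`,
`position_protein_R.tsv`, `group_rates.tsv`, …) plus a `manifest.json`
with row counts and checksums; re-running with the same seed reproduces
the manifest byte for byte.

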