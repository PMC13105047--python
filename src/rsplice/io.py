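"""Readers and writers for the external formats the pipeline touches.

Internal convention everywhere: 1-based inclusive genomic intervals on the
forward (reference) strand, matching the STAR SJ.out.tab dialect.  BED inputs
are converted at this boundary.  Sequences for minus-strand features are
reverse-complemented at extraction time, never stored both ways.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pyfaidx

log = logging.getLogger(__name__)

STRAND_CODES = {0: ".", 1: "+", 2: "-"}
STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}

SJ_COLUMNS = [
    "chrom", "start", "end", "strand_code", "motif_code",
    "annotated", "unique_reads", "multimap_reads", "max_overhang",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def zero_to_one_based(start0: int) -> int:
    """0-based half-open start -> 1-based inclusive position."""
    return start0 + 1


def one_to_zero_based(pos1: int) -> int:
    return pos1 - 1


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, genomic order

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class GenomeAnnotation:
    """Exon structure per transcript, grouped by gene."""

    transcripts: dict[str, TranscriptRecord] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)  # gene -> tids

    def add(self, rec: TranscriptRecord) -> None:
        self.transcripts[rec.transcript_id] = rec
        self.genes.setdefault(rec.gene_id, []).append(rec.transcript_id)

    def validate(self) -> None:
        for rec in self.transcripts.values():
            exons = rec.exons
            for (s, e) in exons:
                if s > e:
                    raise ValueError(
                        f"transcript {rec.transcript_id}: exon {s}-{e} reversed")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"transcript {rec.transcript_id}: exons overlap or "
                        f"are unsorted at {e1}/{s2}")


def read_gtf(path: str | os.PathLike) -> GenomeAnnotation:
    """Parse exon features of a GTF into per-transcript exon lists.

    Introns are derivable as the gaps between consecutive exons (1-based
    inclusive).  A transcript with a single exon yields zero introns.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            disable_infer_genes=True, disable_infer_transcripts=True,
            keep_order=False, merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a mix of exception types
        raise ValueError(f"malformed GTF {path}: {exc}") from exc
    ann = GenomeAnnotation()
    by_tx: dict[str, TranscriptRecord] = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"GTF {path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                f"missing attribute {exc}") from exc
        rec = by_tx.get(tid)
        if rec is None:
            rec = TranscriptRecord(tid, gid, feat.seqid, feat.strand, [])
            by_tx[tid] = rec
        rec.exons.append((feat.start, feat.end))
    for rec in by_tx.values():
        rec.exons.sort()
        ann.add(rec)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Splice-junction tables (STAR SJ.out.tab dialect)


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    start: int  # first intron base, 1-based
    end: int    # last intron base, 1-based
    strand: str  # '+', '-', '.' (unknown)
    unique_reads: int
    multimap_reads: int = 0
    annotated: bool = False
    sample_id: str = ""
    phase: str = ""  # 'nascent' | 'mature'

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_sj_table(path: str | os.PathLike, phase: str,
                  sample_id: str) -> list[SpliceJunction]:
    """Read a 9-column STAR SJ.out.tab file.

    Coordinates stay 1-based inclusive; strand codes are decoded; no read
    filtering happens here (thresholds are applied downstream).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=SJ_COLUMNS,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return []
    int_cols = SJ_COLUMNS[1:]
    try:
        df[int_cols] = df[int_cols].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"SJ table {path}: non-integer field ({exc})") from exc
    if (df["start"] > df["end"]).any():
        raise ValueError(f"SJ table {path}: junction with start > end")
    out = []
    for row in df.itertuples(index=False):
        out.append(SpliceJunction(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            strand=STRAND_CODES.get(int(row.strand_code), "."),
            unique_reads=int(row.unique_reads),
            multimap_reads=int(row.multimap_reads),
            annotated=bool(row.annotated),
            sample_id=sample_id, phase=phase))
    return out


def write_sj_table(junctions: list[SpliceJunction],
                   path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write("\t".join(map(str, [
                j.chrom, j.start, j.end, STRAND_TO_CODE[j.strand], 1,
                int(j.annotated), j.unique_reads, j.multimap_reads, 50,
            ])) + "\n")


# ---------------------------------------------------------------------------
# bedMethyl (BED9+, ENCODE WGBS dialect: col 10 coverage, col 11 percent)


@dataclass(frozen=True)
class MethylationRecord:
    chrom: str
    position: int  # 1-based coordinate of the cytosine
    percent_methylated: float  # 0..100
    coverage: int
    strand: str = "+"


def read_bedmethyl(path: str | os.PathLike) -> list[MethylationRecord]:
    """Read bedMethyl records, converting 0-based starts to 1-based positions.

    Records with a percent outside [0, 100] are rejected; the count of
    rejections is logged as a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 11:
        raise ValueError(f"bedMethyl {path}: expected >= 11 columns")
    out = []
    rejected = 0
    for row in df.itertuples(index=False):
        pct = float(row[10])
        cov = int(row[9])
        if not (0.0 <= pct <= 100.0) or cov < 0:
            rejected += 1
            continue
        out.append(MethylationRecord(
            chrom=str(row[0]), position=zero_to_one_based(int(row[1])),
            percent_methylated=pct, coverage=cov, strand=str(row[5])))
    if rejected:
        log.warning("bedMethyl %s: rejected %d records with invalid "
                    "percent/coverage", path, rejected)
    return out


def write_bedmethyl(records: list[MethylationRecord],
                    path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            start0 = one_to_zero_based(r.position)
            fh.write("\t".join(map(str, [
                r.chrom, start0, start0 + 1, "CpG", 0, r.strand,
                start0, start0 + 1, "0,0,0", r.coverage,
                _fmt_pct(r.percent_methylated),
            ])) + "\n")


def _fmt_pct(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# Expression tables


def read_tpm(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns transcript_id, gene_id, TPM."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "TPM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TPM table {path}: missing columns {sorted(missing)}")
    return df


def gene_tpm(tpm: pd.DataFrame) -> pd.Series:
    """Gene-level TPM: transcript TPMs summed per gene."""
    return tpm.groupby("gene_id")["TPM"].sum()


# ---------------------------------------------------------------------------
# Genome access


class Genome:
    """1-based inclusive windowed access to an indexed FASTA.

    ``fetch(chrom, start, end, strand)`` returns the sense-strand sequence:
    minus-strand requests are reverse-complemented so that position increases
    5'->3' in transcription orientation.
    """

    def __init__(self, path: str | os.PathLike):
        self._fa = pyfaidx.Fasta(str(path))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def contig_length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._fa:
            raise KeyError(f"contig {chrom!r} not in genome")
        if start < 1 or end > len(self._fa[chrom]) or start > end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside contig bounds")
        seq = self._fa[chrom][start - 1:end].seq.upper()
        return reverse_complement(seq) if strand == "-" else seq
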