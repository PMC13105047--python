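"""Constitutive-intron extraction and recursive-splice-junction classification.

An intron is *constitutive* when every isoform of its gene that spans its
interval contains it with identical coordinates, and its interval overlaps
no other distinct intron anywhere in the annotation (either strand).

Nascent splice junctions are then classified against constitutive introns by
strand-aware boundary comparison into four classes: ``basic`` (both
boundaries match the annotated intron), ``RS5`` (recursive 5' splice site
inside the intron, annotated 3'SS), ``RS3`` (annotated 5'SS, recursive 3'SS
inside) and ``nested`` (both boundaries recursive).  Recursive boundaries
must be at least 75 nt from the annotated sites of a host intron at least
150 nt long; candidate recursive junctions must be absent from every mature
sample.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeAnnotation, Genome, SpliceJunction

RS_CLASSES = ("RS5", "RS3", "nested")


@dataclass(frozen=True)
class Intron:
    chrom: str
    start: int  # first intron base, 1-based
    end: int    # last intron base, 1-based
    strand: str
    gene_id: str
    transcript_id: str
    position_class: str  # 'first' | 'middle' | 'last' (transcription order)
    constitutive: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the first intron base in transcription
        orientation (highest coordinate on the minus strand)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class ClassifiedIntron:
    intron: Intron
    rs_class: str  # 'basic' | 'RS5' | 'RS3' | 'nested'
    recursive_5ss: int | None = None
    recursive_3ss: int | None = None
    supporting_junctions: list[SpliceJunction] = field(default_factory=list)

    def validate(self) -> None:
        i = self.intron
        if self.rs_class == "basic":
            assert self.recursive_5ss is None and self.recursive_3ss is None
            assert i.length >= 75
            return
        assert i.length >= 150, "RS host intron shorter than 150 nt"
        if self.rs_class == "RS5":
            assert self.recursive_5ss is not None and self.recursive_3ss is None
        elif self.rs_class == "RS3":
            assert self.recursive_3ss is not None and self.recursive_5ss is None
        else:
            assert self.recursive_5ss is not None and self.recursive_3ss is not None
        if self.recursive_5ss is not None:
            assert abs(self.recursive_5ss - i.five_prime) >= 75
        if self.recursive_3ss is not None:
            assert abs(self.recursive_3ss - i.three_prime) >= 75


def transcript_introns(ann: GenomeAnnotation) -> dict[str, list[Intron]]:
    """Introns per transcript in transcription order with position classes."""
    out: dict[str, list[Intron]] = {}
    for tid, rec in ann.transcripts.items():
        gaps = rec.introns()  # genomic order
        if rec.strand == "-":
            gaps = gaps[::-1]  # transcription order: highest coordinate first
        introns = []
        n = len(gaps)
        for i, (s, e) in enumerate(gaps):
            pos = "first" if i == 0 else ("last" if i == n - 1 else "middle")
            introns.append(Intron(rec.chrom, s, e, rec.strand, rec.gene_id,
                                  tid, pos))
        out[tid] = introns
    return out


def extract_constitutive_introns(
        ann: GenomeAnnotation,
        require_identical_in_spanning: bool = True,
        include_opposite_strand_overlap: bool = True) -> list[Intron]:
    """Select introns that are constitutive across isoforms and overlap no
    other distinct intron interval in the annotation."""
    per_tx = transcript_introns(ann)

    # candidate introns deduplicated by coordinates
    candidates: dict[tuple, Intron] = {}
    for tid in sorted(per_tx):
        for intr in per_tx[tid]:
            candidates.setdefault(intr.key, intr)

    # rule (a): identical in every spanning isoform of the gene
    kept: list[Intron] = []
    for key in sorted(candidates):
        intr = candidates[key]
        ok = True
        if require_identical_in_spanning:
            for tid in ann.genes[intr.gene_id]:
                rec = ann.transcripts[tid]
                lo, hi = rec.span
                if lo <= intr.start and intr.end <= hi:
                    if (intr.start, intr.end) not in set(rec.introns()):
                        ok = False
                        break
        if ok:
            kept.append(intr)

    # rule (b): no overlap with any other distinct intron interval
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    intervals: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for key, intr in candidates.items():
        chrom_key = (intr.chrom if include_opposite_strand_overlap
                     else (intr.chrom, intr.strand))
        if (intr.start, intr.end) not in intervals[chrom_key]:
            intervals[chrom_key].add((intr.start, intr.end))
            trees[chrom_key].addi(intr.start, intr.end + 1)
    out = []
    for intr in kept:
        chrom_key = (intr.chrom if include_opposite_strand_overlap
                     else (intr.chrom, intr.strand))
        hits = trees[chrom_key].overlap(intr.start, intr.end + 1)
        distinct = [h for h in hits
                    if (h.begin, h.end - 1) != (intr.start, intr.end)]
        if not distinct:
            out.append(intr)
    return out


# ---------------------------------------------------------------------------
# classification


def _aggregate(junctions: list[SpliceJunction]) -> dict[tuple, int]:
    """Sum unique reads over samples of the same phase, keyed by junction
    coordinates."""
    agg: dict[tuple, int] = defaultdict(int)
    for j in junctions:
        agg[j.key] += j.unique_reads
    return dict(agg)


def _boundary_case(intron: Intron, start: int, end: int) -> tuple[str, int | None, int | None]:
    """Classify a contained same-strand junction [start, end] against the
    intron by strand-aware boundary comparison.

    Returns (case, recursive_5ss, recursive_3ss) where case is 'exact',
    'RS5', 'RS3' or 'nested'.  Equality of a boundary means canonical;
    recursive boundaries must lie strictly inside the intron.
    """
    five_match = (start == intron.start if intron.strand == "+"
                  else end == intron.end)
    three_match = (end == intron.end if intron.strand == "+"
                   else start == intron.start)
    if five_match and three_match:
        return "exact", None, None
    if intron.strand == "+":
        r5 = None if five_match else start
        r3 = None if three_match else end
    else:
        r5 = None if five_match else end
        r3 = None if three_match else start
    if r5 is not None and r3 is not None:
        return "nested", r5, r3
    if r5 is not None:
        return "RS5", r5, None
    return "RS3", None, r3


def classify_junctions(
        introns: list[Intron],
        nascent_junctions: list[SpliceJunction],
        mature_junctions: list[SpliceJunction],
        min_unique_reads: int = 3,
        min_rs_distance: int = 75,
        min_rs_intron_length: int = 150,
        min_basic_length: int = 75,
) -> tuple[list[ClassifiedIntron], pd.DataFrame]:
    """Classify nascent junctions against constitutive introns.

    Returns one ``ClassifiedIntron`` per (intron, class) observed, plus a
    discard log.  A junction key absent from every mature sample at any read
    depth counts as nascent-unique; only those may provide recursive
    evidence.  Strand-unknown junctions are discarded.
    """
    nascent = _aggregate([j for j in nascent_junctions if j.strand != "."])
    mature_keys = {j.key for j in mature_junctions}
    unknown_strand = [j for j in nascent_junctions if j.strand == "."]

    trees: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
    for idx, intr in enumerate(introns):
        trees[(intr.chrom, intr.strand)].addi(intr.start, intr.end + 1, idx)

    # (intron idx, class) -> evidence
    evidence: dict[tuple[int, str], dict] = {}
    discards = []

    def discard(key, reads, reason):
        discards.append({"chrom": key[0], "start": key[1], "end": key[2],
                         "strand": key[3], "unique_reads": reads,
                         "reason": reason})

    for j in unknown_strand:
        discard(j.key, j.unique_reads, "unknown_strand")

    for key in sorted(nascent):
        reads = nascent[key]
        if reads < min_unique_reads:
            discard(key, reads, "below_read_threshold")
            continue
        chrom, start, end, strand = key
        hits = [h for h in trees[(chrom, strand)].overlap(start, end + 1)
                if introns[h.data].start <= start and end <= introns[h.data].end]
        if not hits:
            discard(key, reads, "no_containing_intron")
            continue
        jct = SpliceJunction(chrom, start, end, strand, reads,
                             phase="nascent")
        matched = False
        for h in hits:
            intr = introns[h.data]
            case, r5, r3 = _boundary_case(intr, start, end)
            if case == "exact":
                if intr.length < min_basic_length:
                    discard(key, reads, "basic_intron_too_short")
                    continue
                _add_evidence(evidence, h.data, "exact", None, None, jct,
                              reads)
                matched = True
                continue
            # recursive evidence requires nascent-unique junctions
            if key in mature_keys:
                discard(key, reads, "present_in_mature")
                continue
            if intr.length < min_rs_intron_length:
                discard(key, reads, "host_intron_too_short")
                continue
            d5 = abs(r5 - intr.five_prime) if r5 is not None else None
            d3 = abs(r3 - intr.three_prime) if r3 is not None else None
            if (d5 is not None and d5 < min_rs_distance) or \
               (d3 is not None and d3 < min_rs_distance):
                discard(key, reads, "recursive_site_too_close")
                continue
            _add_evidence(evidence, h.data, case, r5, r3, jct, reads)
            matched = True
        if not matched and hits:
            continue

    # assemble output: one record per (intron, RS class); basic only when
    # no RS-class junction was seen for the intron
    by_intron: dict[int, dict[str, dict]] = defaultdict(dict)
    for (idx, case), ev in evidence.items():
        by_intron[idx][case] = ev
    out: list[ClassifiedIntron] = []
    for idx in sorted(by_intron):
        cases = by_intron[idx]
        intr = introns[idx]
        rs_cases = [c for c in cases if c != "exact"]
        if rs_cases:
            for case in sorted(rs_cases):
                ev = cases[case]
                ci = ClassifiedIntron(
                    intron=intr, rs_class=case,
                    recursive_5ss=ev["best_r5"], recursive_3ss=ev["best_r3"],
                    supporting_junctions=ev["junctions"])
                ci.validate()
                out.append(ci)
        elif "exact" in cases:
            ev = cases["exact"]
            ci = ClassifiedIntron(intron=intr, rs_class="basic",
                                  supporting_junctions=ev["junctions"])
            ci.validate()
            out.append(ci)
    log = pd.DataFrame(discards, columns=["chrom", "start", "end", "strand",
                                          "unique_reads", "reason"])
    return out, log


def _add_evidence(evidence, idx, case, r5, r3, jct, reads):
    ev = evidence.setdefault((idx, case), {
        "junctions": [], "best_reads": -1, "best_r5": None, "best_r3": None})
    ev["junctions"].append(jct)
    if reads > ev["best_reads"]:
        ev.update(best_reads=reads, best_r5=r5, best_r3=r3)


# ---------------------------------------------------------------------------
# summaries


def junction_length_summary(classified: list[ClassifiedIntron]) -> pd.DataFrame:
    """Per class and junction phase: junction count and median/mean
    junction length; per class: the fraction of host introns that are
    first/middle/last in their transcript."""
    rows = []
    classes = ("basic",) + RS_CLASSES
    by_class = {c: [ci for ci in classified if ci.rs_class == c]
                for c in classes}
    for c in classes:
        cis = by_class[c]
        phases = sorted({j.phase for ci in cis
                         for j in ci.supporting_junctions}) or [""]
        pos = pd.Series([ci.intron.position_class for ci in cis])
        n_host = len(cis)
        for phase in phases:
            lengths = [j.length for ci in cis
                       for j in ci.supporting_junctions
                       if j.phase == phase]
            rows.append({
                "rs_class": c, "phase": phase,
                "n_junctions": len(lengths),
                "median_length": (float(np.median(lengths))
                                  if lengths else np.nan),
                "mean_length": (float(np.mean(lengths))
                                if lengths else np.nan),
                "frac_first": (float((pos == "first").mean())
                               if n_host else np.nan),
                "frac_middle": (float((pos == "middle").mean())
                                if n_host else np.nan),
                "frac_last": (float((pos == "last").mean())
                              if n_host else np.nan),
            })
    return pd.DataFrame(rows)


def motif_at_recursive_sites(classified: list[ClassifiedIntron],
                             genome: Genome) -> pd.DataFrame:
    """Fraction of recursive sites matching AGG[T/C] (AGGU/C in RNA) on the
    sense strand at positions -2..+2 around the site.

    At a recursive 5'SS the tetramer spans the last two removed and first
    two retained bases; at a recursive 3'SS it spans the last two removed
    bases and the first two of the remainder.
    """
    rows = []
    for klass in RS_CLASSES:
        for site_type in ("recursive5", "recursive3"):
            hits = total = edge = 0
            for ci in classified:
                if ci.rs_class != klass:
                    continue
                site = (ci.recursive_5ss if site_type == "recursive5"
                        else ci.recursive_3ss)
                if site is None:
                    continue
                tet = _site_tetramer(genome, ci.intron, site, site_type)
                if tet is None:
                    edge += 1
                    continue
                total += 1
                if tet[:3] == "AGG" and tet[3] in "TC":
                    hits += 1
            rows.append({
                "rs_class": klass, "site_type": site_type, "n_sites": total,
                "n_edge_excluded": edge,
                "fraction_aggu": hits / total if total else np.nan,
            })
    return pd.DataFrame(rows)


def _site_tetramer(genome: Genome, intron: Intron, site: int,
                   site_type: str) -> str | None:
    """Sense-strand tetramer AG|GU-style window around a recursive site."""
    strand = intron.strand
    if site_type == "recursive5":
        # site = first retained base (the G of GU)
        lo, hi = (site - 2, site + 1) if strand == "+" else (site - 1, site + 2)
    else:
        # site = last removed base (the G of AG)
        lo, hi = (site - 1, site + 2) if strand == "+" else (site - 2, site + 1)
    if lo < 1 or hi > genome.contig_length(intron.chrom):
        return None
    return genome.fetch(intron.chrom, lo, hi, strand)
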