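"""Synthetic data generator for the recursive-splicing pipeline.

Emulates the statistical structure the analysis assumes, so every downstream
stage is testable without any download: multi-exon genes with long first
introns, planted AGGU recursive sites inside recursively spliced (RS)
introns, a CG-rich motif flanking the first-intron 5'SS of RS genes, a
purine-diluted pyrimidine tract at their 3'SS, nascent-only recursive
junctions with negative-binomial read support, lower first-exon CpG
methylation for RS genes, a tunable odds ratio coupling first-intron RS to
downstream-intron RS, and an in-vitro binding table with one planted
CG-preferring and one pyrimidine-preferring pseudo-protein.

All randomness flows from a single seeded generator; a seeded run is
bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as rio

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# pyrimidine-tract compositions (A, C, G, T)
PPT_BASE = np.array([0.08, 0.40, 0.07, 0.45])
PPT_PURINE_DILUTED = np.array([0.25, 0.18, 0.12, 0.45])


@dataclass
class SyntheticConfig:
    """Generator parameters.  Defaults are the study conditions used
    throughout the test-suite; see docs/methods.md for the rationale."""

    seed: int
    n_genes: int = 200
    introns_per_gene: tuple[int, int] = (3, 5)  # inclusive range
    # length models (log10 nt)
    first_intron_log10_mean: float = 3.0
    first_intron_log10_sd: float = 0.25
    downstream_intron_log10_mean: float = 2.55
    downstream_intron_log10_sd: float = 0.2
    exon_log10_mean: float = 2.15
    exon_log10_sd: float = 0.1
    min_intron_length: int = 180
    min_exon_length: int = 60
    background_base_probs: tuple[float, float, float, float] = (
        0.3, 0.2, 0.2, 0.3)
    # recursive-splicing structure
    rs_gene_fraction: float = 0.35          # P(first-intron RS)
    downstream_rs_marginal: float = 0.30    # P(any downstream-intron RS)
    coupling_odds_ratio: float = 2.2
    rs_class_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # RS5/RS3/nested
    aggu_fraction: float = 0.6              # fraction of sites with intact AGGU
    min_rs_distance: int = 75
    # planted sequence signal
    cg_motif_strength: float = 0.3
    ppt_purine_dilution: float = 0.5
    rs_length_boost_log10: float = 0.4
    rs_tpm_boost_log10: float = 0.3
    # expression
    tpm_log10_mean: float = 0.8
    tpm_log10_sd: float = 0.5
    # methylation (Beta shape parameters, scaled to percent)
    meth_beta_rs: tuple[float, float] = (2.0, 8.0)
    meth_beta_nonrs: tuple[float, float] = (6.0, 4.0)
    meth_beta_other: tuple[float, float] = (5.0, 5.0)
    cpg_percent_sd: float = 8.0
    cpg_coverage_mean: float = 30.0
    # junction read-count model
    nb_mean: float = 8.0
    nb_dispersion: float = 0.5
    read_floor: int = 1                     # truncation: counts >= read_floor
    n_nascent_samples: int = 2
    n_mature_samples: int = 1
    # in-vitro binding tables
    rbns_k: int = 5
    rbns_n_neutral: int = 6
    # layout
    minus_strand_fraction: float = 0.5
    intergenic_spacer: int = 500
    genes_per_chrom: int = 1000

    def validate(self) -> None:
        probs = [self.rs_gene_fraction, self.downstream_rs_marginal,
                 self.aggu_fraction, self.minus_strand_fraction,
                 self.cg_motif_strength, self.ppt_purine_dilution,
                 *self.rs_class_probs, *self.background_base_probs]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.coupling_odds_ratio <= 0:
            raise ValueError("coupling_odds_ratio must be > 0")
        if abs(sum(self.background_base_probs) - 1.0) > 1e-9:
            raise ValueError("background base probabilities must sum to 1")
        if abs(sum(self.rs_class_probs) - 1.0) > 1e-9:
            raise ValueError("rs_class_probs must sum to 1")
        if self.rs_gene_fraction > 0 or self.downstream_rs_marginal > 0:
            if self.min_intron_length < 2 * self.min_rs_distance + 1:
                raise ValueError(
                    "recursive sites require introns of length >= "
                    f"{2 * self.min_rs_distance + 1}; raise min_intron_length")


@dataclass
class Bundle:
    """Paths of one generated input set plus the intron-level truth table."""

    outdir: Path
    fasta: Path
    gtf: Path
    nascent_sj: list[Path]
    mature_sj: list[Path]
    tpm: Path
    bedmethyl: Path
    rbns: Path
    truth_path: Path
    truth: pd.DataFrame = field(repr=False)
    config: SyntheticConfig = field(repr=False)


# ---------------------------------------------------------------------------
# coupling model


def joint_first_downstream_prob(p1: float, p2: float, psi: float) -> float:
    """P(first RS and downstream RS) for margins p1, p2 and odds ratio psi
    (Plackett construction)."""
    if p1 == 0.0 or p2 == 0.0:
        return 0.0
    if psi == 1.0:
        return p1 * p2
    a = psi - 1.0
    A = 1.0 + a * (p1 + p2)
    disc = A * A - 4.0 * psi * a * p1 * p2
    p11 = (A - math.sqrt(disc)) / (2.0 * a)
    return min(max(p11, 0.0), min(p1, p2))


# ---------------------------------------------------------------------------
# motif planting


def _cg_theta(shift: float, window_len: int, p_c: float, p_g: float) -> float:
    """Solve for the per-pair CG planting probability that raises the
    expected CG-dinucleotide density (overlapping count / (L-1)) by `shift`
    over the background density p_c * p_g."""
    L = window_len
    npairs = L // 2
    pcg = p_c * p_g

    def gain(t: float) -> float:
        even = npairs * (t + (1.0 - t) * pcg)
        odd = max(npairs - 1, 0) * (1.0 - t) ** 2 * pcg
        return (even + odd) / (L - 1) - pcg

    if shift > gain(1.0):
        raise ValueError(
            f"composition_shift {shift} unattainable in a {L}-nt window")
    return brentq(lambda t: gain(t) - shift, 0.0, 1.0)


def _plant_cg_window(arr: np.ndarray, lo: int, hi: int, shift: float,
                     rng: np.random.Generator,
                     bg: np.ndarray) -> None:
    """Resample arr[lo:hi] in place, raising expected CG-dinucleotide density
    by `shift`.  Bases outside [lo, hi) are untouched."""
    L = hi - lo
    if L == 0 or shift == 0.0:
        return
    theta = _cg_theta(shift, L, bg[1], bg[2])
    fresh = rng.choice(4, size=L, p=bg)
    plant = rng.random(L // 2) < theta
    for i, planted in enumerate(plant):
        if planted:
            fresh[2 * i] = 1      # C
            fresh[2 * i + 1] = 2  # G
    arr[lo:hi] = fresh


def plant_motif(sequence: str, window: tuple[int, int],
                composition_shift: float, seed: int) -> str:
    """Return `sequence` with arr[window] resampled so the expected
    CG-dinucleotide density rises by `composition_shift`.

    `window` is a 0-based half-open slice.  Only the window changes; a shift
    of 0 short-circuits and returns the input unchanged.
    """
    lo, hi = window
    if lo < 0 or hi > len(sequence) or lo > hi:
        raise ValueError(f"window {window} out of range for sequence of "
                         f"length {len(sequence)}")
    if composition_shift == 0.0 or hi == lo:
        return sequence
    rng = np.random.default_rng(seed)
    idx = {b: i for i, b in enumerate(BASES)}
    arr = np.array([idx.get(b.upper(), 0) for b in sequence], dtype=np.int64)
    bg = np.full(4, 0.25)
    _plant_cg_window(arr, lo, hi, composition_shift, rng, bg)
    return "".join(BASES[i] for i in arr)


def _resample_composition(arr: np.ndarray, lo: int, hi: int,
                          comp: np.ndarray, rng: np.random.Generator) -> None:
    arr[lo:hi] = rng.choice(4, size=hi - lo, p=comp)


# ---------------------------------------------------------------------------
# generation


def _draw_lengths(rng, n, mu, sd, floor):
    x = np.round(10.0 ** rng.normal(mu, sd, size=n)).astype(int)
    return np.maximum(x, floor)


def _local_to_genomic(a: int, b: int, gi_start: int, gi_end: int,
                      strand: str) -> tuple[int, int]:
    """Map a 1-based local (sense) interval [a, b] within an intron to a
    genomic interval (start <= end)."""
    if strand == "+":
        return gi_start + a - 1, gi_start + b - 1
    return gi_end - b + 1, gi_end - a + 1


def _local_pos_to_genomic(p: int, gi_start: int, gi_end: int,
                          strand: str) -> int:
    return gi_start + p - 1 if strand == "+" else gi_end - p + 1


def generate(config: SyntheticConfig, outdir: str | os.PathLike) -> Bundle:
    """Generate the full input bundle into `outdir` and return its paths
    plus the per-intron truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bg = np.asarray(config.background_base_probs)
    spacer = config.intergenic_spacer
    p1 = config.rs_gene_fraction
    # a gene fraction of zero disables RS everywhere (degenerate contract)
    p2 = config.downstream_rs_marginal if p1 > 0 else 0.0
    p11 = joint_first_downstream_prob(p1, p2, config.coupling_odds_ratio)
    p_down_given_first = p11 / p1 if p1 > 0 else 0.0
    p_down_given_nofirst = (p2 - p11) / (1 - p1) if p1 < 1 else 0.0
    rs_ppt = ((1 - config.ppt_purine_dilution) * PPT_BASE
              + config.ppt_purine_dilution * PPT_PURINE_DILUTED)

    nested_min_len = 2 * config.min_rs_distance + 90  # room for two sites

    chrom_arrays: dict[str, list[np.ndarray]] = {}
    chrom_cursor: dict[str, int] = {}
    truth_rows = []
    gtf_lines = []
    tpm_rows = []
    junction_rows = []  # (chrom, start, end, strand, annotated, gene, kind)
    exon_rows = []      # for methylation: (gene, tx, chrom, strand, idx, s, e, group)

    for g in range(config.n_genes):
        chrom = f"chrS{g // config.genes_per_chrom + 1}"
        if chrom not in chrom_arrays:
            chrom_arrays[chrom] = [rng.choice(4, size=spacer, p=bg)]
            chrom_cursor[chrom] = spacer
        gene_id = f"GENE{g:05d}"
        tx_id = f"TX{g:05d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_introns = int(rng.integers(config.introns_per_gene[0],
                                     config.introns_per_gene[1] + 1))
        n_exons = n_introns + 1

        first_rs = bool(rng.random() < p1)
        p_down = p_down_given_first if first_rs else p_down_given_nofirst
        down_rs = bool(rng.random() < p_down) if n_introns > 1 else False

        exon_lens = _draw_lengths(rng, n_exons, config.exon_log10_mean,
                                  config.exon_log10_sd, config.min_exon_length)
        first_mu = (config.first_intron_log10_mean
                    + (config.rs_length_boost_log10 if first_rs else 0.0))
        first_len = int(_draw_lengths(rng, 1, first_mu,
                                      config.first_intron_log10_sd,
                                      max(config.min_intron_length,
                                          nested_min_len))[0])
        down_lens = _draw_lengths(rng, n_introns - 1,
                                  config.downstream_intron_log10_mean,
                                  config.downstream_intron_log10_sd,
                                  config.min_intron_length)
        # which introns carry recursive sites (transcription-order indices);
        # the downstream RS intron is drawn longer, mirroring the length
        # preference of recursive splicing
        rs_down_idx = None
        if down_rs:
            rs_down_idx = int(rng.integers(1, n_introns))
            down_lens[rs_down_idx - 1] = _draw_lengths(
                rng, 1, config.downstream_intron_log10_mean
                + config.rs_length_boost_log10,
                config.downstream_intron_log10_sd,
                max(config.min_intron_length, nested_min_len))[0]
        intron_lens = np.concatenate([[first_len], down_lens]).astype(int)

        rs_introns: dict[int, str] = {}
        if first_rs:
            rs_introns[0] = _draw_class(rng, config, intron_lens[0],
                                        nested_min_len)
        if rs_down_idx is not None:
            rs_introns[rs_down_idx] = _draw_class(
                rng, config, intron_lens[rs_down_idx], nested_min_len)

        # --- sense-strand sequence ------------------------------------
        total_len = int(exon_lens.sum() + intron_lens.sum())
        arr = rng.choice(4, size=total_len, p=bg)
        # sense offsets of each exon/intron (0-based half-open)
        ex_off, in_off = [], []
        cur = 0
        for i in range(n_exons):
            ex_off.append((cur, cur + int(exon_lens[i])))
            cur += int(exon_lens[i])
            if i < n_introns:
                in_off.append((cur, cur + int(intron_lens[i])))
                cur += int(intron_lens[i])

        # CG-rich motif around the first-intron 5'SS of RS genes (-30..+50)
        if first_rs and config.cg_motif_strength > 0:
            i1 = in_off[0][0]
            _plant_cg_window(arr, i1 - 30, i1 + 51,
                             config.cg_motif_strength, rng, bg)

        # pyrimidine tracts: -50..-5 upstream of every 3'SS
        for i, (lo, hi) in enumerate(in_off):
            comp = rs_ppt if (first_rs and i == 0) else PPT_BASE
            _resample_composition(arr, hi - 50, hi - 4, comp, rng)

        # recursive AGGU ratchet points + site bookkeeping
        site_info: dict[int, dict] = {}
        for i, klass in rs_introns.items():
            lo, hi = in_off[i]
            L = int(intron_lens[i])
            d = config.min_rs_distance
            if klass == "nested":
                r1 = int(rng.integers(d + 1, L - d - 80 + 1))
                r2 = int(rng.integers(r1 + 80, L - d + 1))
                sites = [r1, r2]
            else:
                sites = [int(rng.integers(d + 1, L - d + 1))]
            planted = []
            for r in sites:
                keep = bool(rng.random() < config.aggu_fraction)
                planted.append(keep)
                if keep:
                    # AG ends the removed segment, GU starts the remainder
                    arr[lo + r - 3:lo + r + 1] = [0, 2, 2, 3]
            site_info[i] = {"class": klass, "sites": sites,
                            "planted": planted, "lo": lo, "hi": hi}

        # canonical dinucleotides last so they are always intact
        for lo, hi in in_off:
            arr[lo:lo + 2] = [2, 3]      # GT
            arr[hi - 2:hi] = [0, 2]      # AG

        # --- genomic placement ----------------------------------------
        g0 = chrom_cursor[chrom] + 1  # 1-based genomic start of gene block
        if strand == "+":
            chrom_arrays[chrom].append(arr)
        else:
            chrom_arrays[chrom].append(3 - arr[::-1])  # reverse complement
        chrom_cursor[chrom] += total_len
        chrom_arrays[chrom].append(rng.choice(4, size=spacer, p=bg))
        chrom_cursor[chrom] += spacer
        g_end = g0 + total_len - 1

        def to_genomic(off_lo: int, off_hi: int) -> tuple[int, int]:
            # sense offsets (0-based half-open) -> genomic 1-based inclusive
            if strand == "+":
                return g0 + off_lo, g0 + off_hi - 1
            return g_end - off_hi + 1, g_end - off_lo

        exon_g = [to_genomic(lo, hi) for lo, hi in ex_off]
        intron_g = [to_genomic(lo, hi) for lo, hi in in_off]

        # --- GTF -------------------------------------------------------
        attr = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
        gtf_lines.append("\t".join(map(str, [
            chrom, "rsplice_sim", "gene", g0, g_end, ".", strand, ".",
            f'gene_id "{gene_id}";'])))
        gtf_lines.append("\t".join(map(str, [
            chrom, "rsplice_sim", "transcript", g0, g_end, ".", strand, ".",
            attr])))
        for (s, e) in sorted(exon_g):
            gtf_lines.append("\t".join(map(str, [
                chrom, "rsplice_sim", "exon", s, e, ".", strand, ".", attr])))

        # --- junctions & truth ----------------------------------------
        for i in range(n_introns):
            gi_s, gi_e = intron_g[i]
            L = int(intron_lens[i])
            junction_rows.append((chrom, gi_s, gi_e, strand, 1, gene_id,
                                  "canonical"))
            klass, r5, r3, p5, p3 = "basic", None, None, None, None
            if i in site_info:
                inf = site_info[i]
                klass = inf["class"]
                if klass == "RS5":
                    r = inf["sites"][0]
                    a, b = _local_to_genomic(r, L, gi_s, gi_e, strand)
                    junction_rows.append((chrom, a, b, strand, 0, gene_id,
                                          "RS5"))
                    r5 = _local_pos_to_genomic(r, gi_s, gi_e, strand)
                    p5 = inf["planted"][0]
                elif klass == "RS3":
                    r = inf["sites"][0]
                    a, b = _local_to_genomic(1, r - 1, gi_s, gi_e, strand)
                    junction_rows.append((chrom, a, b, strand, 0, gene_id,
                                          "RS3"))
                    r3 = _local_pos_to_genomic(r - 1, gi_s, gi_e, strand)
                    p3 = inf["planted"][0]
                else:  # nested
                    r1, r2 = inf["sites"]
                    a, b = _local_to_genomic(r1, r2 - 1, gi_s, gi_e, strand)
                    junction_rows.append((chrom, a, b, strand, 0, gene_id,
                                          "nested"))
                    r5 = _local_pos_to_genomic(r1, gi_s, gi_e, strand)
                    r3 = _local_pos_to_genomic(r2 - 1, gi_s, gi_e, strand)
                    p5, p3 = inf["planted"]
            position = ("first" if i == 0
                        else "last" if i == n_introns - 1 else "middle")
            truth_rows.append({
                "gene_id": gene_id, "transcript_id": tx_id, "chrom": chrom,
                "strand": strand, "intron_index": i,
                "position_class": position, "start": gi_s, "end": gi_e,
                "length": L, "rs_class": klass,
                "recursive_5ss": r5, "recursive_3ss": r3,
                "aggu_5_planted": p5, "aggu_3_planted": p3,
                "first_rs": first_rs, "downstream_rs": down_rs,
            })

        # --- expression & methylation bookkeeping ---------------------
        tpm = 10.0 ** rng.normal(
            config.tpm_log10_mean
            + (config.rs_tpm_boost_log10 if first_rs else 0.0),
            config.tpm_log10_sd)
        tpm_rows.append((tx_id, gene_id, round(float(tpm), 4)))
        for tx_idx in range(n_exons):
            s, e = exon_g[tx_idx]
            if tx_idx == 0:
                group = "first_rs" if first_rs else "first_nonrs"
            else:
                group = "other"
            exon_rows.append((gene_id, tx_id, chrom, strand, tx_idx, s, e,
                              group))

    # --- write FASTA ---------------------------------------------------
    fasta_path = outdir / "genome.fa"
    chrom_seqs: dict[str, np.ndarray] = {}
    with open(fasta_path, "w") as fh:
        for chrom in sorted(chrom_arrays):
            full = np.concatenate(chrom_arrays[chrom])
            chrom_seqs[chrom] = full
            seq = _BASE_BYTES[full].tobytes().decode()
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    if (fasta_path.parent / "genome.fa.fai").exists():
        (fasta_path.parent / "genome.fa.fai").unlink()

    # --- GTF / TPM -----------------------------------------------------
    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + "\n")
    tpm_path = outdir / "expression.tsv"
    pd.DataFrame(tpm_rows, columns=["transcript_id", "gene_id", "TPM"]) \
        .to_csv(tpm_path, sep="\t", index=False)

    # --- splice-junction tables ----------------------------------------
    jdf = pd.DataFrame(junction_rows, columns=[
        "chrom", "start", "end", "strand", "annotated", "gene_id", "kind"])
    jdf = jdf.sort_values(["chrom", "start", "end"], kind="mergesort") \
             .reset_index(drop=True)
    nb_n = 1.0 / config.nb_dispersion
    nb_p = nb_n / (nb_n + config.nb_mean)

    def _sj_counts(n: int) -> np.ndarray:
        c = rng.negative_binomial(nb_n, nb_p, size=n)
        return np.maximum(c, config.read_floor)

    nascent_paths, mature_paths = [], []
    for s in range(config.n_nascent_samples):
        path = outdir / f"nascent_{s + 1}.SJ.out.tab"
        _write_sj(jdf, _sj_counts(len(jdf)), path)
        nascent_paths.append(path)
    mature_mask = jdf["annotated"] == 1
    mdf = jdf[mature_mask].reset_index(drop=True)
    for s in range(config.n_mature_samples):
        path = outdir / f"mature_{s + 1}.SJ.out.tab"
        _write_sj(mdf, _sj_counts(len(mdf)), path)
        mature_paths.append(path)

    # --- methylation ----------------------------------------------------
    meth_records = []
    beta = {"first_rs": config.meth_beta_rs,
            "first_nonrs": config.meth_beta_nonrs,
            "other": config.meth_beta_other}
    for (gene_id, tx_id, chrom, strand, idx, s, e, group) in exon_rows:
        a, b = beta[group]
        exon_mean = 100.0 * rng.beta(a, b)
        seq = chrom_seqs[chrom][s - 1:e]
        cg = np.flatnonzero((seq[:-1] == 1) & (seq[1:] == 2))
        for off in cg:
            pct = float(np.clip(rng.normal(exon_mean, config.cpg_percent_sd),
                                0.0, 100.0))
            cov = int(rng.poisson(config.cpg_coverage_mean)) + 1
            meth_records.append(rio.MethylationRecord(
                chrom=chrom, position=s + int(off),
                percent_methylated=round(pct, 2), coverage=cov))
    meth_records.sort(key=lambda r: (r.chrom, r.position))
    bed_path = outdir / "methylation.bed"
    rio.write_bedmethyl(meth_records, bed_path)

    # --- RBNS ------------------------------------------------------------
    rbns_path = outdir / "rbns.tsv"
    _write_rbns(rng, config, rbns_path)

    # --- truth -----------------------------------------------------------
    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    _write_config(config, outdir / "config.txt")

    return Bundle(outdir=outdir, fasta=fasta_path, gtf=gtf_path,
                  nascent_sj=nascent_paths, mature_sj=mature_paths,
                  tpm=tpm_path, bedmethyl=bed_path, rbns=rbns_path,
                  truth_path=truth_path, truth=truth, config=config)


def _draw_class(rng, config: SyntheticConfig, length: int,
                nested_min_len: int) -> str:
    klass = ["RS5", "RS3", "nested"][
        int(rng.choice(3, p=np.asarray(config.rs_class_probs)))]
    if klass == "nested" and length < nested_min_len:
        klass = "RS5"
    return klass


def _write_sj(jdf: pd.DataFrame, counts: np.ndarray, path: Path) -> None:
    out = pd.DataFrame({
        "chrom": jdf["chrom"],
        "start": jdf["start"],
        "end": jdf["end"],
        "strand_code": jdf["strand"].map(rio.STRAND_TO_CODE),
        "motif_code": 1,
        "annotated": jdf["annotated"],
        "unique_reads": counts,
        "multimap_reads": 0,
        "max_overhang": 50,
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def _write_rbns(rng, config: SyntheticConfig, path: Path) -> None:
    k = config.rbns_k
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    cg_counts = np.array([km.count("CG") for km in kmers], dtype=float)
    pyr_frac = np.array([(km.count("C") + km.count("T")) / k for km in kmers])
    rows = []
    proteins = (["CGBIND1", "PYBIND1"]
                + [f"RBPN{i + 1}" for i in range(config.rbns_n_neutral)])
    for prot in proteins:
        for conc, scale in (("20", 1.0), ("320", 1.3)):
            noise = np.exp(rng.normal(0.0, 0.05, size=len(kmers)))
            if prot == "CGBIND1":
                r = noise * (1.0 + scale * 2.0 * cg_counts)
            elif prot == "PYBIND1":
                r = noise * (1.0 + scale * 1.2 * pyr_frac)
            else:
                r = noise
            for km, val in zip(kmers, r):
                rows.append((prot, conc, km, round(float(val), 5)))
    pd.DataFrame(rows, columns=["protein", "concentration", "kmer", "R"]) \
        .to_csv(path, sep="\t", index=False)


def _write_config(config: SyntheticConfig, path: Path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key} = {val}\n")
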