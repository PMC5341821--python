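"""Readers and writers for VCF, BED, FASTA and tab-delimited tables.

VCF parsing goes through :mod:`cyvcf2`; FASTA through :mod:`pyfaidx`.  BED
and the simple TSV dialects (multi-sample SNV table, gene-model table) are
small enough to read with pandas directly.
"""

from __future__ import annotations

import logging
import os
import textwrap
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    BASES,
    Cohort,
    GeneModel,
    GenomicInterval,
    ReferenceSequence,
    SnvRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed input file (message names the offending line)."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, sample_id: str) -> list[SnvRecord]:
    """Read PASS biallelic SNVs from one VCF as records for ``sample_id``.

    Rows whose FILTER is neither PASS nor missing, indels, and multi-allelic
    rows are skipped (a summary count is logged).  Depth is taken from
    ``INFO/DP`` and allele fraction from ``INFO/AF`` when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"{path}: unreadable VCF header ({exc})") from exc

    records: list[SnvRecord] = []
    n_skipped = 0
    for i, v in enumerate(vcf):
        try:
            if v.FILTER is not None:  # None means PASS / '.'
                n_skipped += 1
                continue
            if len(v.ALT) != 1 or not v.is_snp:
                n_skipped += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if ref not in BASES or alt not in BASES:
                n_skipped += 1
                continue
            depth = v.INFO.get("DP")
            af = v.INFO.get("AF")
            records.append(
                SnvRecord(
                    sample_id=sample_id,
                    chrom=normalize_chrom(v.CHROM),
                    pos=v.POS,
                    ref=ref,
                    alt=alt,
                    depth=int(depth) if depth is not None else None,
                    alt_fraction=float(af) if af is not None else None,
                )
            )
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"{path}: bad VCF body row {i + 1} ({exc})") from exc
    if n_skipped:
        logger.info("%s: skipped %d non-PASS / non-SNV / multi-allelic rows", path, n_skipped)
    return records


def write_vcf(records: Sequence[SnvRecord], path: str | os.PathLike) -> None:
    """Write records as a minimal single-sample VCF 4.2 (uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = []
            if r.depth is not None:
                info.append(f"DP={r.depth}")
            if r.alt_fraction is not None:
                info.append(f"AF={r.alt_fraction:.4f}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike, label: str | None = None) -> list[GenomicInterval]:
    """Read BED3/BED5/BED6 into sorted intervals (0-based half-open).

    ``label``, when given, is used as the interval name for BED3 rows that
    lack one (convenient for naming track provenance).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else label
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | os.PathLike,
    chr_prefix: bool = False,
) -> None:
    """Write intervals as BED; columns extend to 6 when name/score/strand set."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            chrom = f"chr{iv.chrom}" if chr_prefix else iv.chrom
            cols = [chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# multi-sample SNV TSV
# ---------------------------------------------------------------------------

def read_snv_table(path: str | os.PathLike, genome_length: int = 3_000_000_000) -> Cohort:
    """Read a multi-sample SNV TSV (columns: sample, chrom, pos, ref, alt
    [, depth, alt_fraction]) into a :class:`Cohort`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df = df.rename(columns={"sample": "sample_id"})
    return Cohort(df, genome_length=genome_length)


def write_snv_table(cohort: Cohort, path: str | os.PathLike) -> None:
    df = cohort.df.rename(columns={"sample_id": "sample"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> ReferenceSequence:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return ReferenceSequence({name: str(fa[name][:]) for name in fa.keys()})


def write_fasta(ref: ReferenceSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ref.seqs):
            fh.write(f">{chrom}\n")
            fh.write("\n".join(textwrap.wrap(ref.seqs[chrom], width)) + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a TSV with one row per feature interval.

    Columns: ``gene, chrom, strand, tss, feature, start, end`` with
    ``start/end`` 0-based half-open; ``feature`` may be empty for rows that
    only declare the gene (chrom/strand/TSS).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    required = {"gene", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        g = genes.get(row.gene)
        if g is None:
            g = GeneModel(row.gene, str(row.chrom), row.strand, int(row.tss))
            genes[row.gene] = g
        feature = getattr(row, "feature", None)
        if feature and not pd.isna(feature):
            iv = GenomicInterval(normalize_chrom(str(row.chrom)), int(row.start), int(row.end))
            g.features.setdefault(str(feature), []).append(iv)
    return list(genes.values())


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        if not g.features:
            rows.append((g.gene, g.chrom, g.strand, g.tss, "", np.nan, np.nan))
        for label, ivs in g.features.items():
            for iv in ivs:
                rows.append((g.gene, g.chrom, g.strand, g.tss, label, iv.start, iv.end))
    pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "tss", "feature", "start", "end"]
    ).to_csv(path, sep="\t", index=False)
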