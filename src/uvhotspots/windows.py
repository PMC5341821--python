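"""Heuristic fixed-window cross-sample cluster scan.

A width-``w`` window slides at 1 bp steps over the sample-merged SNV events;
every start whose window holds at least ``k`` events (events, not distinct
samples: a single recurrently mutated position in four patients counts four
times) is reported, and overlapping reported windows are merged and
re-summarised.  Downstream filters restrict windows to uniquely mappable
sequence and to "heuristic promoters": open chromatin (DNase hypersensitive
clusters with 50 bp flanks) supported by at least three distinct ChIP-seq
peak sources.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import (
    Cohort,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    TrackSet,
    merge_intervals,
    overlap_query,
    positions_in_intervals,
    score_one_intervals,
)

#: promoter span used when a gene model lacks an explicit promoter feature:
#: [TSS - upstream, TSS + downstream) around the 1-based TSS.
DEFAULT_PROMOTER_SPAN = (1000, 100)


@dataclass
class ClusterWindow:
    """A merged above-threshold window with its cross-sample summary."""

    interval: GenomicInterval
    snv_count: int
    n_samples: int
    snv_positions: list[tuple[int, str]]  # (1-based pos, sample_id)
    annotations: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()
    in_dhs_flank: bool | None = None
    chip_peak_count: int | None = None
    mappable: bool | None = None


def filter_mappable(cohort: Cohort, mappable20: Sequence[GenomicInterval]) -> Cohort:
    """Retain SNVs lying in 20-mer uniqueness intervals with score exactly 1."""
    if mappable20 is None:
        raise ConfigurationError("mappable20 track is required")
    unique = score_one_intervals(mappable20)
    if len(cohort) == 0:
        return cohort
    mask = positions_in_intervals(
        cohort.df["chrom"].tolist(), cohort.df["pos"].to_numpy(), unique
    )
    return cohort.subset_positions(mask)


def _summarise(chrom: str, start: int, end: int, pos: np.ndarray, samples: np.ndarray) -> ClusterWindow:
    sel = (pos - 1 >= start) & (pos - 1 < end)
    members = sorted(zip(pos[sel].tolist(), samples[sel].tolist()))
    return ClusterWindow(
        interval=GenomicInterval(chrom, start, end),
        snv_count=int(sel.sum()),
        n_samples=len({s for _, s in members}),
        snv_positions=members,
    )


def scan_windows(cohort: Cohort, w: int, k: int) -> list[ClusterWindow]:
    """All merged windows of width ``w`` holding >= ``k`` cross-sample events.

    For sorted event positions ``p_1 <= ... <= p_m`` a window ``[s, s+w)``
    (0-based start ``s``) holds >= k events iff some run ``j..j+k-1``
    satisfies ``p_{j+k-1} - p_j < w`` with
    ``s in [p_{j+k-1} - w + 1, p_j]`` (positions on the 0-based axis).  The
    union of those start ranges, dilated by the window width and clipped at
    the chromosome origin, is exactly the union of all above-threshold
    windows, so merging follows from interval union without enumerating
    every start.
    """
    if w < 1 or k < 1:
        raise ValueError("w and k must be >= 1")
    out: list[ClusterWindow] = []
    for chrom, grp in cohort.df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)  # sorted by Cohort contract
        samples = grp["sample_id"].to_numpy()
        if len(pos) < k:
            continue
        p0 = pos - 1
        first = p0[: len(p0) - k + 1]
        last = p0[k - 1 :]
        ok = last - first < w
        if not ok.any():
            continue
        # window-interval union: [max(0, last - w + 1), first + w) per run
        starts = np.maximum(0, last[ok] - w + 1)
        ends = first[ok] + w
        ivs = [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
        for merged in merge_intervals(ivs):
            out.append(_summarise(chrom, merged.start, merged.end, pos, samples))
    return out


def subset_heuristic_promoter(
    windows: Sequence[ClusterWindow],
    tracks: TrackSet,
    flank: int = 50,
    min_chip: int = 3,
) -> list[ClusterWindow]:
    """Windows in open chromatin with multi-factor ChIP support.

    Retains windows that (a) overlap a DHS interval expanded by ``flank`` bp
    each side and (b) overlap >= ``min_chip`` ChIP peaks with distinct
    source labels.  Flags are recorded on every returned window.
    """
    tracks.require("dhs", "chip")
    dhs = [iv.expand(flank) for iv in tracks.get("dhs")]
    chip = tracks.get("chip")
    kept: list[ClusterWindow] = []
    for win in windows:
        in_dhs = bool(overlap_query(dhs, win.interval))
        labels = {iv.name for iv in overlap_query(chip, win.interval)}
        win = replace(win, in_dhs_flank=in_dhs, chip_peak_count=len(labels))
        if in_dhs and len(labels) >= min_chip:
            kept.append(win)
    return kept


def gene_feature_intervals(
    gene: GeneModel, promoter_span: tuple[int, int] = DEFAULT_PROMOTER_SPAN
) -> list[tuple[str, GenomicInterval]]:
    """Labelled feature intervals of a gene, synthesising a default promoter
    ``[TSS - upstream, TSS + downstream)`` (strand-aware) when the model has
    no explicit promoter feature."""
    pairs = [(label, iv) for label, ivs in gene.features.items() for iv in ivs]
    if "promoter" not in gene.features:
        up, down = promoter_span
        tss0 = gene.tss - 1
        if gene.strand == "+":
            start, end = tss0 - up, tss0 + down
        else:
            start, end = tss0 - down + 1, tss0 + up + 1
        if end > 0:
            pairs.append(("promoter", GenomicInterval(gene.chrom, max(0, start), end)))
    return pairs


def annotate_features(
    window: ClusterWindow,
    genes: Sequence[GeneModel],
    promoter_span: tuple[int, int] = DEFAULT_PROMOTER_SPAN,
) -> ClusterWindow:
    """Label a window with every overlapping gene feature (multi-label).

    A window straddling, say, a promoter and the 5'UTR of the divergent gene
    carries both labels; windows overlapping no feature are ``intergenic``.
    """
    labels: set[str] = set()
    hit_genes: set[str] = set()
    for gene in genes:
        if gene.chrom != window.interval.chrom:
            continue
        for label, iv in gene_feature_intervals(gene, promoter_span):
            if iv.overlaps(window.interval):
                labels.add(label)
                hit_genes.add(gene.gene)
    if not labels:
        labels = {"intergenic"}
    return replace(window, annotations=frozenset(labels), genes=frozenset(hit_genes))


def find_bidirectional_promoters(
    genes: Sequence[GeneModel], max_gap: int = 1000
) -> list[tuple[GeneModel, GeneModel]]:
    """Divergent gene pairs: same chromosome, opposite strands, TSSs within
    ``max_gap`` bp.  Pairs are unordered and reported once, sorted by name."""
    pairs: list[tuple[GeneModel, GeneModel]] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes = sorted(chrom_genes, key=lambda g: (g.tss, g.gene))
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1 :]:
                if b.tss - a.tss > max_gap:
                    break
                if a.strand != b.strand:
                    pairs.append(tuple(sorted((a, b), key=lambda g: g.gene)))
    return sorted(pairs, key=lambda p: (p[0].gene, p[1].gene))
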