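"""Domain types, coordinate conventions and interval algebra.

All internal coordinates are 0-based half-open ``[start, end)`` (BED
convention).  VCF-style 1-based positions appear only in :class:`SnvRecord`
(``pos``), mirroring how variant callers report them; conversion to the
internal axis is ``pos - 1``.  Chromosome names are normalised by stripping
a leading ``chr`` prefix so that tracks of mixed provenance (UCSC vs TCGA
naming) can be intersected safely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Track labels recognised by :class:`TrackSet`.
TRACK_LABELS = ("dhs", "chip", "blacklist", "mappable20", "mappable100", "state")

#: Gene-feature labels used for window annotation.
FEATURE_LABELS = (
    "promoter",
    "five_prime_utr",
    "cds",
    "intron",
    "three_prime_utr",
    "splice_site",
)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (``chr1`` -> ``1``)."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide variant in one sample.

    ``pos`` is 1-based (VCF convention); the internal half-open interval of
    the variant is ``[pos - 1, pos)``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    alt_fraction: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (need start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos1: int) -> bool:
        """Does the interval contain a 1-based position?"""
        return self.start <= pos1 - 1 < self.end

    def expand(self, flank: int) -> "GenomicInterval":
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)


SNV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_fraction"]


class Cohort:
    """A multi-sample collection of somatic SNVs.

    Stored as a :class:`pandas.DataFrame` sorted by ``(chrom, pos,
    sample_id)`` so iteration order is deterministic.  Exact duplicates of
    ``(sample_id, chrom, pos, alt)`` are collapsed with a warning because
    duplicated rows would double-count every scan statistic downstream;
    conflicting calls (same sample and position, different alt) violate the
    one-call-per-site contract and raise.

    Parameters
    ----------
    snvs
        Iterable of :class:`SnvRecord` or a DataFrame with columns
        ``sample_id, chrom, pos, ref, alt[, depth, alt_fraction]``.
    sample_ids
        Ordered sample universe.  Defaults to the samples present in
        ``snvs``; samples with zero calls can be declared explicitly.
    genome_length
        Callable genome size in bp used for per-sample rate estimates
        (default 3e9, the approximate human genome).
    """

    def __init__(
        self,
        snvs: Iterable[SnvRecord] | pd.DataFrame = (),
        sample_ids: Sequence[str] | None = None,
        genome_length: int = 3_000_000_000,
    ):
        if isinstance(snvs, pd.DataFrame):
            df = snvs.copy()
        else:
            df = pd.DataFrame(
                [
                    (s.sample_id, s.chrom, s.pos, s.ref, s.alt, s.depth, s.alt_fraction)
                    for s in snvs
                ],
                columns=SNV_COLUMNS,
            )
        if df.empty:
            df = pd.DataFrame(columns=SNV_COLUMNS)
        for col in ("depth", "alt_fraction"):
            if col not in df.columns:
                df[col] = np.nan
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise ValueError("SNV positions must be 1-based (>= 1)")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("found SNV rows with ref == alt")

        n0 = len(df)
        df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "alt"])
        if len(df) < n0:
            warnings.warn(
                f"collapsed {n0 - len(df)} duplicate SNV rows (same sample/chrom/pos/alt)",
                stacklevel=2,
            )
        dup_site = df.duplicated(subset=["sample_id", "chrom", "pos"])
        if dup_site.any():
            bad = df[dup_site].iloc[0]
            raise ValueError(
                "conflicting calls at one site within a sample: "
                f"{bad['sample_id']} {bad['chrom']}:{bad['pos']}"
            )
        df = df.sort_values(["chrom", "pos", "sample_id"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        observed = list(dict.fromkeys(self.df["sample_id"]))
        if sample_ids is None:
            self.sample_ids = tuple(sorted(observed))
        else:
            self.sample_ids = tuple(dict.fromkeys(sample_ids))
            missing = set(observed) - set(self.sample_ids)
            if missing:
                raise ValueError(f"SNVs from undeclared samples: {sorted(missing)}")
        self.genome_length = int(genome_length)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def records(self) -> Iterable[SnvRecord]:
        for row in self.df.itertuples(index=False):
            yield SnvRecord(
                row.sample_id,
                row.chrom,
                int(row.pos),
                row.ref,
                row.alt,
                None if pd.isna(row.depth) else int(row.depth),
                None if pd.isna(row.alt_fraction) else float(row.alt_fraction),
            )

    def per_sample_counts(self) -> pd.Series:
        counts = self.df["sample_id"].value_counts()
        return counts.reindex(self.sample_ids, fill_value=0)

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def subset_samples(self, keep: Sequence[str]) -> "Cohort":
        keep = [s for s in self.sample_ids if s in set(keep)]
        return Cohort(
            self.df[self.df["sample_id"].isin(keep)],
            sample_ids=keep,
            genome_length=self.genome_length,
        )

    def subset_positions(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            self.df[np.asarray(mask, dtype=bool)],
            sample_ids=self.sample_ids,
            genome_length=self.genome_length,
        )


@dataclass
class GeneModel:
    """A gene with its TSS and labelled feature intervals.

    ``features`` maps each feature label (see :data:`FEATURE_LABELS`) to a
    list of intervals on the gene's chromosome.  ``tss`` is 1-based.
    """

    gene: str
    chrom: str
    strand: str
    tss: int
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be + or -")
        for label, ivs in self.features.items():
            if label not in FEATURE_LABELS:
                raise ValueError(f"gene {self.gene}: unknown feature label {label!r}")
            for iv in ivs:
                if normalize_chrom(iv.chrom) != self.chrom:
                    raise ValueError(
                        f"gene {self.gene}: feature on {iv.chrom}, gene on {self.chrom}"
                    )


class ReferenceSequence:
    """Uppercase DNA, one string per chromosome.

    Out-of-range lookups return ``N`` so flank queries at contig edges are
    always defined.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = {normalize_chrom(c): s.upper() for c, s in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.seqs

    def length(self, chrom: str) -> int:
        return len(self.seqs[normalize_chrom(chrom)])

    def base(self, chrom: str, pos1: int) -> str:
        """Base at a 1-based position (``N`` outside the contig)."""
        seq = self.seqs[normalize_chrom(chrom)]
        i = pos1 - 1
        if i < 0 or i >= len(seq):
            return "N"
        return seq[i]

    def context(self, chrom: str, pos1: int) -> tuple[str, str, str]:
        """(5' neighbour, base, 3' neighbour) around a 1-based position."""
        return (
            self.base(chrom, pos1 - 1),
            self.base(chrom, pos1),
            self.base(chrom, pos1 + 1),
        )

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence on the internal 0-based half-open axis."""
        return self.seqs[normalize_chrom(chrom)][max(0, start) : end]


class TrackSet:
    """Named interval collections driving every filter step.

    Recognised labels: ``dhs``, ``chip``, ``blacklist``, ``mappable20``,
    ``mappable100``, ``state``.  Intervals within a track are kept sorted by
    ``(chrom, start)``.  ``chip`` intervals must carry a ``name`` (the
    peak-source label, e.g. the assayed factor) so distinct peaks are
    countable; ``mappable*`` intervals carry a uniqueness score in [0, 1].
    """

    def __init__(self, tracks: Mapping[str, Sequence[GenomicInterval]] | None = None):
        self._tracks: dict[str, list[GenomicInterval]] = {}
        for label, ivs in (tracks or {}).items():
            self.set(label, ivs)

    def set(self, label: str, intervals: Sequence[GenomicInterval]) -> None:
        if label not in TRACK_LABELS:
            raise ValueError(f"unknown track label {label!r}; expected one of {TRACK_LABELS}")
        ivs = sorted(intervals, key=lambda iv: (normalize_chrom(iv.chrom), iv.start))
        ivs = [replace(iv, chrom=normalize_chrom(iv.chrom)) for iv in ivs]
        if label == "chip" and any(iv.name is None for iv in ivs):
            raise ValueError("chip intervals must carry a peak-source name")
        if label.startswith("mappable"):
            for iv in ivs:
                if iv.score is None or not (0.0 <= iv.score <= 1.0):
                    raise ValueError(f"{label} intervals need a score in [0, 1]")
        self._tracks[label] = ivs

    def __contains__(self, label: str) -> bool:
        return label in self._tracks

    def get(self, label: str) -> list[GenomicInterval]:
        if label not in self._tracks:
            raise KeyError(f"track {label!r} not loaded")
        return self._tracks[label]

    def require(self, *labels: str) -> None:
        missing = [l for l in labels if l not in self._tracks]
        if missing:
            raise ConfigurationError(f"required track(s) missing: {missing}")

    def labels(self) -> list[str]:
        return sorted(self._tracks)


class ConfigurationError(RuntimeError):
    """A required track or parameter is missing."""


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def _group_by_chrom(xs: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in xs:
        out.setdefault(normalize_chrom(iv.chrom), []).append(iv)
    return out


def merge_intervals(
    xs: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals within ``gap`` bp into a minimal disjoint set.

    ``gap=0`` merges overlapping or abutting intervals, so the union of the
    output equals the union of the input.  Names/scores are dropped (merged
    intervals are new objects).  Output is sorted by ``(chrom, start)``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom in sorted(_group_by_chrom(xs)):
        ivs = sorted(_group_by_chrom(xs)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def overlap_query(
    xs: Sequence[GenomicInterval], q: GenomicInterval
) -> list[GenomicInterval]:
    """All intervals of ``xs`` with nonzero overlap with ``q`` (half-open)."""
    qc = normalize_chrom(q.chrom)
    return [
        iv
        for iv in xs
        if normalize_chrom(iv.chrom) == qc and iv.start < q.end and q.start < iv.end
    ]


def positions_in_intervals(
    chroms: Sequence[str], pos1: np.ndarray, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: does each 1-based position fall inside the interval union?

    Vectorised per chromosome over the merged interval set.
    """
    pos1 = np.asarray(pos1, dtype=np.int64)
    chrom_arr = np.asarray([normalize_chrom(c) for c in chroms])
    mask = np.zeros(len(pos1), dtype=bool)
    merged = merge_intervals(intervals) if intervals else []
    by_chrom = _group_by_chrom(merged)
    for chrom, ivs in by_chrom.items():
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        p0 = pos1[sel] - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, len(ivs) - 1)])
        mask[np.where(sel)[0]] = ok
    return mask


def interval_contained(q: GenomicInterval, cover: Sequence[GenomicInterval]) -> bool:
    """Is ``q`` fully contained in the union of ``cover``?"""
    for iv in merge_intervals(cover) if cover else []:
        if normalize_chrom(iv.chrom) == normalize_chrom(q.chrom):
            if iv.start <= q.start and q.end <= iv.end:
                return True
    return False


def score_one_intervals(track: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Subset of a scored track with score exactly 1 (unique mappability)."""
    return [iv for iv in track if iv.score == 1.0]
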