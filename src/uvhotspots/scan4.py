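"""Background-corrected genome-wide cluster test on k-scans.

SNVs from all samples are merged onto one coordinate axis per chromosome.
Every run of ``k`` adjacent events (default 4, a "4-scan") is scored by its
spanned width; a local mutation density (events per sample per Mb in sliding
1 Mb windows) is attached to each scan, and log-widths are regressed on a
quadratic in the log density.  Scans whose widths fall far below the
regression prediction — tighter clusters than the local rate explains — get
small one-sided normal p-values on the residual scale; Benjamini-Hochberg
q-values below a cutoff define significant scans, which are merged into
disjoint hotspots by interval overlap.

Recurrent same-position events across samples are retained on the merged
axis, so a position mutated in four samples yields a width-1 scan: the
strongest possible signal, as for classic promoter-hotspot recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core import (
    Cohort,
    ConfigurationError,
    GenomicInterval,
    TrackSet,
    interval_contained,
    merge_intervals,
    overlap_query,
    score_one_intervals,
)
from .stats import bh_qvalues
from .windows import ClusterWindow


@dataclass
class KScan:
    """A run of ``k`` adjacent merged SNV events."""

    chrom: str
    k: int
    first_pos: int  # 1-based position of first member
    last_pos: int   # 1-based position of last member
    members: tuple[tuple[int, str], ...]  # (pos, sample_id), sorted
    local_count: float | None = None  # events per sample per Mb at this locus
    residual: float | None = None
    p_value: float | None = None
    q_value: float | None = None

    @property
    def width(self) -> int:
        return self.last_pos - self.first_pos + 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.first_pos - 1, self.last_pos)


@dataclass
class WidthModel:
    """Quadratic log-log width model ``log(width + 0.5) ~ 1 + x + x^2`` with
    ``x = log(c + c_offset)``; ``sigma`` is the residual SD (n - 3 df)."""

    beta: np.ndarray
    sigma: float
    n: int
    r_squared: float
    c_offset: float = 0.5

    def predict(self, c: np.ndarray) -> np.ndarray:
        x = np.log(np.asarray(c, dtype=float) + self.c_offset)
        return self.beta[0] + self.beta[1] * x + self.beta[2] * x * x


@dataclass
class Hotspot:
    """Disjoint interval formed by merging overlapping significant scans."""

    interval: GenomicInterval
    n_variants: int
    n_samples: int
    member_scans: list[KScan]
    min_q: float
    annotations: frozenset[str] = frozenset()

    @property
    def center(self) -> float:
        return (self.interval.start + self.interval.end) / 2


MergedEvents = dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, sample)


def merge_samples(cohort: Cohort) -> MergedEvents:
    """All samples' events on one axis per chromosome, ordered by
    ``(pos, sample_id)``; duplicate positions across samples are retained."""
    out: MergedEvents = {}
    for chrom, grp in cohort.df.groupby("chrom", sort=True):
        out[chrom] = (
            grp["pos"].to_numpy(dtype=np.int64),
            grp["sample_id"].to_numpy(),
        )
    return out


def enumerate_kscans(events: MergedEvents, k: int = 4) -> list[KScan]:
    """Every run of ``k`` adjacent events; a chromosome with ``m`` events
    yields ``m - k + 1`` overlapping scans."""
    if k < 2:
        raise ValueError("k must be >= 2")
    scans: list[KScan] = []
    for chrom in sorted(events):
        pos, samples = events[chrom]
        m = len(pos)
        for j in range(m - k + 1):
            members = tuple(zip(pos[j : j + k].tolist(), samples[j : j + k].tolist()))
            scans.append(
                KScan(
                    chrom=chrom,
                    k=k,
                    first_pos=int(pos[j]),
                    last_pos=int(pos[j + k - 1]),
                    members=members,
                )
            )
    return scans


class BackgroundTrack:
    """Piecewise event density from sliding windows (events/sample/Mb).

    Windows of ``window`` bp start every ``step`` bp; a query position is
    assigned the window whose centre is nearest (the window "containing" it
    under the sliding tiling).
    """

    def __init__(
        self,
        events: MergedEvents,
        n_samples: int,
        chrom_lengths: dict[str, int] | None = None,
        window: int = 1_000_000,
        step: int = 100_000,
    ):
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        self.window = int(window)
        self.step = int(step)
        self.n_samples = int(n_samples)
        self._counts: dict[str, np.ndarray] = {}
        for chrom, (pos, _) in events.items():
            length = None if chrom_lengths is None else chrom_lengths.get(chrom)
            if length is None:
                length = int(pos.max()) if len(pos) else self.window
            n_win = max(1, (max(length - self.window, 0)) // self.step + 1)
            starts = np.arange(n_win) * self.step
            p0 = pos - 1
            counts = np.searchsorted(p0, starts + self.window, side="left") - np.searchsorted(
                p0, starts, side="left"
            )
            self._counts[chrom] = counts.astype(float)

    def c(self, chrom: str, pos1: int) -> float:
        """Local density (events per sample per Mb) at a 1-based position."""
        counts = self._counts.get(chrom)
        if counts is None:
            return 0.0
        mid = pos1 - 1
        idx = int(round((mid - self.window / 2) / self.step))
        idx = min(max(idx, 0), len(counts) - 1)
        return counts[idx] / self.n_samples / (self.window / 1e6)

    def window_count(self, chrom: str, index: int) -> float:
        return self._counts[chrom][index]


def local_background(
    events: MergedEvents,
    n_samples: int,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 1_000_000,
    step: int = 100_000,
) -> BackgroundTrack:
    return BackgroundTrack(events, n_samples, chrom_lengths, window, step)


def attach_background(scans: Sequence[KScan], background: BackgroundTrack) -> list[KScan]:
    """Assign each scan the density of the window containing its midpoint."""
    out = []
    for s in scans:
        mid = (s.first_pos + s.last_pos) // 2
        out.append(replace(s, local_count=background.c(s.chrom, mid)))
    return out


def filter_scans(scans: Sequence[KScan], tracks: TrackSet) -> list[KScan]:
    """Drop scans overlapping the blacklist or not fully contained in
    uniquely 100-mer-mappable sequence."""
    tracks.require("blacklist", "mappable100")
    blacklist = tracks.get("blacklist")
    mappable = score_one_intervals(tracks.get("mappable100"))
    kept = []
    for s in scans:
        iv = s.interval
        if overlap_query(blacklist, iv):
            continue
        if not interval_contained(iv, mappable):
            continue
        kept.append(s)
    return kept


def fit_width_model(
    scans: Sequence[KScan],
    c_offset: float = 0.5,
    min_scans: int = 100,
    robust: bool = False,
) -> WidthModel:
    """OLS of ``log(width + 0.5)`` on ``[1, x, x^2]``, ``x = log(c + c_offset)``.

    ``sigma`` is the residual SD with an n - 3 degrees-of-freedom correction;
    ``robust=True`` replaces it with the scaled median absolute deviation,
    which resists inflation by a handful of extreme (true-cluster) scans.
    """
    import statsmodels.api as sm

    widths = np.array([s.width for s in scans], dtype=float)
    cs = np.array(
        [s.local_count if s.local_count is not None else np.nan for s in scans]
    )
    finite = np.isfinite(widths) & np.isfinite(cs)
    widths, cs = widths[finite], cs[finite]
    n = len(widths)
    if n < min_scans:
        raise ValueError(f"need >= {min_scans} scans with finite predictors, got {n}")
    y = np.log(widths + 0.5)
    x = np.log(cs + c_offset)
    if np.ptp(x) == 0 or np.allclose(np.var(x), 0):
        raise ValueError("degenerate design: local densities are all equal")
    X = np.column_stack([np.ones(n), x, x * x])
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    if robust:
        sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    else:
        sigma = float(np.sqrt(np.sum(resid**2) / (n - 3)))
    if sigma <= 0:
        raise ValueError("residual scale is zero; widths carry no variation")
    return WidthModel(
        beta=np.asarray(fit.params),
        sigma=sigma,
        n=n,
        r_squared=float(fit.rsquared),
        c_offset=c_offset,
    )


def score_scans(scans: Sequence[KScan], model: WidthModel) -> list[KScan]:
    """One-sided left-tail normal p-values on residual widths, then BH
    q-values over all scored scans.  Small widths give negative residuals
    and hence small p."""
    if model.sigma <= 0:
        raise ValueError("model sigma must be positive")
    cs = np.array([s.local_count for s in scans], dtype=float)
    y = np.log(np.array([s.width for s in scans], dtype=float) + 0.5)
    resid = y - model.predict(cs)
    p = norm.cdf(resid / model.sigma)
    q = bh_qvalues(p)
    return [
        replace(s, residual=float(r), p_value=float(pi), q_value=float(qi))
        for s, r, pi, qi in zip(scans, resid, p, q)
    ]


def merge_hotspots(scans: Sequence[KScan], q_max: float = 0.01) -> list[Hotspot]:
    """Merge significant scans (q < ``q_max``) that share genomic positions
    into disjoint hotspots (connected components of the overlap graph)."""
    sig = [s for s in scans if s.q_value is not None and s.q_value < q_max]
    sig.sort(key=lambda s: (s.chrom, s.first_pos, s.last_pos))
    hotspots: list[Hotspot] = []
    group: list[KScan] = []

    def flush(group: list[KScan]):
        if not group:
            return
        first = min(s.first_pos for s in group)
        last = max(s.last_pos for s in group)
        events = {m for s in group for m in s.members}
        hotspots.append(
            Hotspot(
                interval=GenomicInterval(group[0].chrom, first - 1, last),
                n_variants=len(events),
                n_samples=len({sample for _, sample in events}),
                member_scans=list(group),
                min_q=min(s.q_value for s in group),
            )
        )

    cur_chrom, cur_last = None, None
    for s in sig:
        # overlap on the inclusive position axis: share at least one base
        if group and s.chrom == cur_chrom and s.first_pos <= cur_last:
            group.append(s)
            cur_last = max(cur_last, s.last_pos)
        else:
            flush(group)
            group = [s]
            cur_chrom, cur_last = s.chrom, s.last_pos
    flush(group)
    return hotspots


def restrict_promoter_hotspots(
    hotspots: Sequence[Hotspot],
    tracks: TrackSet,
    flank: int = 50,
    min_chip: int = 3,
) -> list[Hotspot]:
    """Proximal-promoter-enriched subset: hotspots overlapping uniquely
    20-mer-mappable sequence, within ``flank`` bp of a DHS cluster, and
    covered by >= ``min_chip`` distinct ChIP peak sources."""
    tracks.require("dhs", "chip", "mappable20")
    dhs = [iv.expand(flank) for iv in tracks.get("dhs")]
    chip = tracks.get("chip")
    mappable = score_one_intervals(tracks.get("mappable20"))
    kept = []
    for h in hotspots:
        if not overlap_query(mappable, h.interval):
            continue
        if not overlap_query(dhs, h.interval):
            continue
        labels = {iv.name for iv in overlap_query(chip, h.interval)}
        if len(labels) < min_chip:
            continue
        kept.append(h)
    return kept


def summarize_hotspots(
    hotspots: Sequence[Hotspot],
    heuristic_windows: Sequence[ClusterWindow] | None = None,
) -> dict:
    """Summary statistics: count, mean width / variants / samples, annotation
    fractions, and (optionally) the fraction of heuristic windows recovered
    by at least one hotspot."""
    summary: dict = {"n_hotspots": len(hotspots)}
    if not hotspots:
        summary.update(
            mean_width=0.0, mean_n_variants=0.0, mean_n_samples=0.0, annotation_fractions={}
        )
        if heuristic_windows is not None:
            summary["heuristic_overlap_fraction"] = 0.0
        return summary
    summary["mean_width"] = float(np.mean([h.interval.width for h in hotspots]))
    summary["mean_n_variants"] = float(np.mean([h.n_variants for h in hotspots]))
    summary["mean_n_samples"] = float(np.mean([h.n_samples for h in hotspots]))
    labels: dict[str, int] = {}
    n_annotated = sum(1 for h in hotspots if h.annotations)
    for h in hotspots:
        for lab in h.annotations:
            labels[lab] = labels.get(lab, 0) + 1
    summary["annotation_fractions"] = (
        {lab: cnt / n_annotated for lab, cnt in sorted(labels.items())} if n_annotated else {}
    )
    if heuristic_windows is not None:
        ivs = [h.interval for h in hotspots]
        hit = sum(
            1 for w in heuristic_windows if overlap_query(ivs, w.interval)
        )
        summary["heuristic_overlap_fraction"] = (
            hit / len(heuristic_windows) if heuristic_windows else 0.0
        )
    return summary
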