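"""Synthetic melanoma-like mutation cohorts with planted hotspots.

The generator emulates the study conditions the detection pipeline is built
for: a cohort of ~40 samples with heterogeneous genome-wide SNV loads
(log-normal across samples), megabase-scale regional background-rate
variation (piecewise-constant gamma multipliers per 1 Mb block, matching the
granularity of the scan's background estimator), a UV mutation spectrum
(C→T / G→A at dipyrimidines with a configurable fraction of tandem CC→TT /
GG→AA events emitted as two adjacent records, the way variant callers
report them), and recurrent cross-sample clusters planted inside designated
promoter-like intervals that matching synthetic DHS / ChIP tracks overlap.

Randomness follows one root seed; child streams are derived per component
(reference, loads, positions, planted hotspots, tracks) so changing, say,
the number of decoy peaks never perturbs the cohort draws.

Within a sample, independently placed events are kept at least 2 bp apart,
so the only tandem adjacent pairs are the deliberately planted dinucleotide
events and ground truth identifies every pair exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BASES, Cohort, GenomicInterval, ReferenceSequence, TrackSet

_B = {b: ord(b) for b in "ACGT"}


@dataclass
class PlantedHotspot:
    """Ground-truth recurrent cluster: each sample hits the span
    independently with ``per_sample_hit_prob`` (cross-sample recurrence)."""

    chrom: str
    center: int  # 0-based internal coordinate
    span: int = 15
    per_sample_hit_prob: float = 0.25
    in_promoter: bool = True

    def __post_init__(self):
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if not 0 <= self.per_sample_hit_prob <= 1:
            raise ValueError("per_sample_hit_prob must lie in [0, 1]")

    @property
    def start(self) -> int:
        return self.center - self.span // 2

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class TrackSpec:
    """Counts/widths for the synthetic track layer."""

    dhs_halfwidth: int = 100
    dhs_decoys: int = 20
    dhs_decoy_width: int = 200
    chip_labels: tuple[str, ...] = ("TF_A", "TF_B", "TF_C")
    chip_decoys: int = 40
    chip_decoy_width: int = 150
    blacklist_n: int = 5
    blacklist_width: int = 5000
    map_gap_n: int = 10
    map_gap_width: int = 1000
    planted_margin: int = 2000  # random intervals stay this far from planted spans


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``load_median``/``load_sigma`` parameterise a log-normal per-sample SNV
    load in mutations per full genome (``full_genome_length`` bp); loads are
    scaled to the simulated chromosome sizes.  The defaults (median 1e5 per
    3 Gb, log-SD 0.5) give the tens-of-mutations-per-Mb loads typical of
    UV-exposed melanoma genomes.  ``uv_fraction`` and ``dinuc_fraction``
    default to the canonical UV spectrum (97% dipyrimidine C→T/G→A, 12% of
    UV events as tandem dinucleotides).
    """

    seed: int
    n_samples: int = 40
    chrom_lengths: dict = field(default_factory=lambda: {"1": 10_000_000})
    load_median: float = 100_000.0
    load_sigma: float = 0.5
    full_genome_length: float = 3.0e9
    block_size: int = 1_000_000
    regional_shape: float = 3.0  # gamma shape for per-block multipliers (mean 1)
    block_multipliers: dict | None = None  # chrom -> list, overrides the gamma draw
    uv_fraction: float = 0.97
    dinuc_fraction: float = 0.12
    gc_fraction: float = 0.41
    hotspots: list[PlantedHotspot] = field(default_factory=list)
    track_spec: TrackSpec = field(default_factory=TrackSpec)

    def __post_init__(self):
        for name in ("uv_fraction", "dinuc_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for chrom, length in self.chrom_lengths.items():
            if length < 10_000:
                raise ValueError(f"chromosome {chrom} shorter than 10 kb")
        for h in self.hotspots:
            if h.chrom not in self.chrom_lengths:
                raise ValueError(f"hotspot on unknown chromosome {h.chrom}")
            if h.start < 0 or h.end > self.chrom_lengths[h.chrom]:
                raise ValueError(f"hotspot at {h.chrom}:{h.center} outside chromosome")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


@dataclass
class SimulationResult:
    cohort: Cohort
    tracks: TrackSet
    truth_hotspots: pd.DataFrame
    truth_snvs: pd.DataFrame
    block_multipliers: dict


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("reference", "loads", "positions", "hotspots", "tracks")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def simulate_reference(config: SimulationConfig) -> ReferenceSequence:
    """I.i.d. bases at the configured GC fraction; deterministic per seed."""
    rng = _child_rngs(config.seed)["reference"]
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seqs = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
        seqs[chrom] = codes.tobytes().decode()
    return ReferenceSequence(seqs)


# ---------------------------------------------------------------------------
# sequence-context site pools
# ---------------------------------------------------------------------------

class _SitePools:
    """Per-chromosome UV-eligible and tandem-dinucleotide site indices."""

    def __init__(self, ref: ReferenceSequence, chrom: str):
        b = np.frombuffer(ref.seqs[chrom].encode(), dtype=np.uint8)
        isC, isG = b == _B["C"], b == _B["G"]
        isT, isA = b == _B["T"], b == _B["A"]
        pyr, pur = isC | isT, isA | isG
        nb_pyr = np.zeros_like(pyr)
        nb_pyr[1:] |= pyr[:-1]
        nb_pyr[:-1] |= pyr[1:]
        nb_pur = np.zeros_like(pur)
        nb_pur[1:] |= pur[:-1]
        nb_pur[:-1] |= pur[1:]
        self.uv_sites = np.where((isC & nb_pyr) | (isG & nb_pur))[0]
        self.uv_is_c = isC[self.uv_sites]
        dinuc = (isC[:-1] & isC[1:]) | (isG[:-1] & isG[1:])
        self.dinuc_sites = np.where(dinuc)[0]  # left member index
        self.dinuc_is_c = isC[self.dinuc_sites]
        self.seq_codes = b

    def pool(self, kind: str) -> np.ndarray:
        return self.uv_sites if kind == "uv" else self.dinuc_sites


KIND_UV, KIND_DINUC, KIND_OTHER, KIND_HOTSPOT = "uv", "dinuc", "other", "hotspot"


def _draw_other(
    rng: np.random.Generator,
    pools: _SitePools | None,
    lo: int,
    hi: int,
    size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform positions with uniform non-UV substitutions (rejection keeps
    the non-UV channel literally non-UV)."""
    pos = rng.integers(lo, hi, size=size)
    alt_idx = rng.integers(0, 3, size=size)
    if pools is None:
        refs = np.full(size, "A")
        alts = np.full(size, "C")
        return pos, refs, alts
    for _ in range(100):
        refs = pools.seq_codes[pos]
        others = np.array(
            [[o for o in BASES if o != b] for b in BASES]
        )  # indexed by base rank
        rank = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), refs)
        alts = others[rank, alt_idx]
        refs_ch = np.frombuffer(refs.tobytes(), dtype="S1").astype(str)
        uv_like = np.zeros(size, dtype=bool)
        in_uv_pool = np.isin(pos, pools.uv_sites)
        uv_like |= (refs_ch == "C") & (alts == "T") & in_uv_pool
        uv_like |= (refs_ch == "G") & (alts == "A") & in_uv_pool
        if not uv_like.any():
            return pos, refs_ch, alts
        n_bad = int(uv_like.sum())
        pos[uv_like] = rng.integers(lo, hi, size=n_bad)
        alt_idx[uv_like] = rng.integers(0, 3, size=n_bad)
    raise RuntimeError("rejection sampling for non-UV substitutions did not converge")


@dataclass
class _Unit:
    """One mutational event: a single SNV or a tandem pair (2 records)."""

    kind: str
    chrom: str
    block: int  # flat block index (for redraws)
    pos: int  # 0-based; pair occupies pos and pos+1
    ref: str
    alt: str
    hotspot_id: int | None = None

    @property
    def record_positions(self) -> tuple[int, ...]:
        return (self.pos, self.pos + 1) if self.kind == KIND_DINUC else (self.pos,)


def _redraw_unit(
    rng: np.random.Generator,
    unit: _Unit,
    pools: _SitePools | None,
    block_bounds: tuple[int, int],
    hotspot: PlantedHotspot | None,
) -> _Unit:
    lo, hi = block_bounds
    if unit.kind == KIND_HOTSPOT and hotspot is not None:
        lo, hi = hotspot.start, hotspot.end
    if unit.kind in (KIND_UV, KIND_HOTSPOT) and pools is not None:
        sites = pools.uv_sites
        sel = sites[(sites >= lo) & (sites < hi)]
        if len(sel) == 0:
            raise ValueError("no UV-eligible sites available for redraw")
        i = int(rng.choice(sel))
        is_c = pools.seq_codes[i] == _B["C"]
        unit.pos, unit.ref, unit.alt = i, ("C" if is_c else "G"), ("T" if is_c else "A")
    elif unit.kind == KIND_DINUC and pools is not None:
        sites = pools.dinuc_sites
        sel = sites[(sites >= lo) & (sites < hi - 1)]
        if len(sel) == 0:
            raise ValueError("no dinucleotide sites available for redraw")
        i = int(rng.choice(sel))
        is_c = pools.seq_codes[i] == _B["C"]
        unit.pos, unit.ref, unit.alt = i, ("C" if is_c else "G"), ("T" if is_c else "A")
    else:
        pos, refs, alts = _draw_other(rng, pools, lo, hi, 1)
        unit.pos, unit.ref, unit.alt = int(pos[0]), str(refs[0]), str(alts[0])
    return unit


def _resolve_conflicts(
    rng: np.random.Generator,
    units: list[_Unit],
    pools_by_chrom: dict[str, _SitePools | None],
    blocks: list[tuple[str, int, int]],
    hotspots: Sequence[PlantedHotspot],
    max_iter: int = 50,
) -> list[_Unit]:
    """Enforce >= 2 bp separation between a sample's independent events."""
    for _ in range(max_iter):
        expanded = []
        for ui, u in enumerate(units):
            for p in u.record_positions:
                expanded.append((u.chrom, p, ui))
        expanded.sort()
        offenders: set[int] = set()
        for (c1, p1, u1), (c2, p2, u2) in zip(expanded, expanded[1:]):
            if c1 == c2 and u1 != u2 and p2 - p1 <= 1:
                a, b = units[u1], units[u2]
                if a.kind == KIND_HOTSPOT and b.kind != KIND_HOTSPOT:
                    offenders.add(u2)
                elif b.kind == KIND_HOTSPOT and a.kind != KIND_HOTSPOT:
                    offenders.add(u1)
                else:
                    offenders.add(max(u1, u2))
        if not offenders:
            return units
        for ui in sorted(offenders):
            u = units[ui]
            chrom, lo, hi = blocks[u.block]
            hs = hotspots[u.hotspot_id] if u.hotspot_id is not None else None
            _redraw_unit(rng, u, pools_by_chrom[u.chrom], (lo, hi), hs)
    # give up on stragglers rather than loop forever (astronomically rare)
    return [u for i, u in enumerate(units) if i not in offenders]


def simulate_cohort(
    config: SimulationConfig, ref: ReferenceSequence | None = None
) -> SimulationResult:
    """Generate a cohort, matching tracks and ground truth.

    With ``ref=None`` the generator runs in positions-only mode: every
    background event is a uniform placeholder substitution and planted hits
    are uniform within their span.  That mode supports scan-statistic tests,
    which depend only on positions; spectrum analyses need a reference.
    """
    rngs = _child_rngs(config.seed)
    chroms = sorted(config.chrom_lengths)
    pools_by_chrom: dict[str, _SitePools | None] = {
        c: (_SitePools(ref, c) if ref is not None else None) for c in chroms
    }

    # --- flat 1 Mb blocks with regional multipliers --------------------------
    blocks: list[tuple[str, int, int]] = []
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        for s in range(0, L, config.block_size):
            blocks.append((chrom, s, min(s + config.block_size, L)))
    rng_pos = rngs["positions"]
    if config.block_multipliers is not None:
        mult = np.array(
            [
                config.block_multipliers[c][s // config.block_size]
                for c, s, _ in blocks
            ],
            dtype=float,
        )
    elif config.regional_shape is None:
        mult = np.ones(len(blocks))
    else:
        shape = config.regional_shape
        mult = rng_pos.gamma(shape, 1.0 / shape, size=len(blocks))
    block_mult: dict[str, list[float]] = {}
    for (chrom, s, _), m in zip(blocks, mult):
        block_mult.setdefault(chrom, []).append(float(m))

    base_w = np.array([m * (e - s) for (c, s, e), m in zip(blocks, mult)], dtype=float)

    def _block_weights(kind: str) -> np.ndarray:
        if kind == KIND_OTHER or ref is None:
            w = base_w
        else:
            sizes = []
            for (chrom, s, e), m in zip(blocks, mult):
                pool = pools_by_chrom[chrom].pool("uv" if kind == KIND_UV else "dinuc")
                sizes.append(m * (np.searchsorted(pool, e) - np.searchsorted(pool, s)))
            w = np.array(sizes, dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"no eligible sites for event kind {kind!r}")
        return w / tot

    weights = {k: _block_weights(k) for k in (KIND_UV, KIND_DINUC, KIND_OTHER)}

    # --- per-sample loads ----------------------------------------------------
    rng_loads = rngs["loads"]
    scale = config.genome_length / config.full_genome_length
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    if config.load_median <= 0:
        loads = {s: 0 for s in sample_ids}
    else:
        loads = {
            s: int(round(rng_loads.lognormal(np.log(config.load_median), config.load_sigma) * scale))
            for s in sample_ids
        }

    # --- planted hotspot hits ------------------------------------------------
    rng_hot = rngs["hotspots"]
    hits_by_sample: dict[str, list[tuple[int, PlantedHotspot]]] = {s: [] for s in sample_ids}
    n_hits = [0] * len(config.hotspots)
    for hid, h in enumerate(config.hotspots):
        mask = rng_hot.random(config.n_samples) < h.per_sample_hit_prob
        for si, hit in enumerate(mask):
            if hit:
                hits_by_sample[sample_ids[si]].append((hid, h))
                n_hits[hid] += 1

    # --- background events per sample ---------------------------------------
    all_units: dict[str, list[_Unit]] = {}
    uv, dn = config.uv_fraction, config.dinuc_fraction
    kind_probs = (
        [uv * (1 - dn), uv * dn, 1 - uv] if ref is not None else [0.0, 0.0, 1.0]
    )
    for s in sample_ids:
        n = loads[s]
        units: list[_Unit] = []
        kind_counts = rng_pos.multinomial(n, kind_probs)
        for kind, count in zip((KIND_UV, KIND_DINUC, KIND_OTHER), kind_counts):
            if count == 0:
                continue
            per_block = rng_pos.multinomial(count, weights[kind])
            for bi, nb in enumerate(per_block):
                if nb == 0:
                    continue
                chrom, lo, hi = blocks[bi]
                pools = pools_by_chrom[chrom]
                if kind == KIND_OTHER or pools is None:
                    pos, refs, alts = _draw_other(rng_pos, pools, lo, hi, nb)
                    for p, r, a in zip(pos, refs, alts):
                        units.append(_Unit(KIND_OTHER, chrom, bi, int(p), str(r), str(a)))
                else:
                    pool = pools.pool("uv" if kind == KIND_UV else "dinuc")
                    sel = pool[(pool >= lo) & (pool < (hi if kind == KIND_UV else hi - 1))]
                    if nb > len(sel):
                        raise ValueError(
                            f"sample {s}: requested {nb} {kind} events in block "
                            f"{chrom}:{lo}-{hi} but only {len(sel)} eligible sites exist"
                        )
                    chosen = rng_pos.choice(sel, size=nb, replace=False)
                    for i in chosen:
                        is_c = pools.seq_codes[i] == _B["C"]
                        units.append(
                            _Unit(
                                kind,
                                chrom,
                                bi,
                                int(i),
                                "C" if is_c else "G",
                                "T" if is_c else "A",
                            )
                        )
        # planted hits for this sample
        for hid, h in hits_by_sample[s]:
            bi = next(
                i for i, (c, lo, hi) in enumerate(blocks) if c == h.chrom and lo <= h.center < hi
            )
            pools = pools_by_chrom[h.chrom]
            if pools is not None:
                sel = pools.uv_sites[(pools.uv_sites >= h.start) & (pools.uv_sites < h.end)]
                if len(sel) == 0:  # degenerate span without context; fall back
                    p = int(rng_hot.integers(h.start, h.end))
                    r = chr(pools.seq_codes[p])
                    a = {"C": "T", "G": "A", "A": "G", "T": "C"}[r]
                else:
                    p = int(rng_hot.choice(sel))
                    r = "C" if pools.seq_codes[p] == _B["C"] else "G"
                    a = "T" if r == "C" else "A"
            else:
                p = int(rng_hot.integers(h.start, h.end))
                r, a = "A", "C"
            units.append(_Unit(KIND_HOTSPOT, h.chrom, bi, p, r, a, hotspot_id=hid))
        units = _resolve_conflicts(rng_pos, units, pools_by_chrom, blocks, config.hotspots)
        all_units[s] = units

    # --- assemble records + ground truth ------------------------------------
    rows, truth_rows = [], []
    pair_counter = 0
    for s in sample_ids:
        for u in all_units[s]:
            if u.kind == KIND_DINUC:
                pair_counter += 1
                for off in (0, 1):
                    rows.append((s, u.chrom, u.pos + 1 + off, u.ref, u.alt, np.nan, np.nan))
                    truth_rows.append(
                        (s, u.chrom, u.pos + 1 + off, u.ref, u.alt, u.kind, pair_counter, None)
                    )
            else:
                rows.append((s, u.chrom, u.pos + 1, u.ref, u.alt, np.nan, np.nan))
                truth_rows.append((s, u.chrom, u.pos + 1, u.ref, u.alt, u.kind, None, u.hotspot_id))
    cohort = Cohort(
        pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_fraction"],
        ),
        sample_ids=sample_ids,
        genome_length=config.genome_length,
    )
    truth_snvs = pd.DataFrame(
        truth_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "kind", "pair_id", "hotspot_id"],
    )
    truth_hotspots = pd.DataFrame(
        [
            (
                hid,
                h.chrom,
                h.center,
                h.span,
                h.start,
                h.end,
                h.per_sample_hit_prob,
                h.in_promoter,
                n_hits[hid],
            )
            for hid, h in enumerate(config.hotspots)
        ],
        columns=[
            "hotspot_id",
            "chrom",
            "center",
            "span",
            "start",
            "end",
            "per_sample_hit_prob",
            "in_promoter",
            "n_hits",
        ],
    )

    tracks = _simulate_tracks(config, rngs["tracks"])
    return SimulationResult(cohort, tracks, truth_hotspots, truth_snvs, block_mult)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _random_intervals_avoiding(
    rng: np.random.Generator,
    chrom_lengths: dict,
    n: int,
    width: int,
    forbidden: list[GenomicInterval],
    margin: int,
) -> list[GenomicInterval]:
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    p = lens / lens.sum()
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n and attempts < 100 * max(n, 1):
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=p))]
        L = chrom_lengths[chrom]
        if L <= width:
            continue
        start = int(rng.integers(0, L - width))
        cand = GenomicInterval(chrom, start, start + width)
        grown = cand.expand(margin)
        if any(grown.overlaps(f) for f in forbidden):
            continue
        out.append(cand)
    if len(out) < n:
        raise RuntimeError("could not place random track intervals away from planted spans")
    return out


def _simulate_tracks(config: SimulationConfig, rng: np.random.Generator) -> TrackSet:
    ts = config.track_spec
    planted = [
        GenomicInterval(h.chrom, max(0, h.start), h.end) for h in config.hotspots
    ]
    promoter_like = [h for h in config.hotspots if h.in_promoter]

    dhs = [
        GenomicInterval(
            h.chrom,
            max(0, h.center - ts.dhs_halfwidth),
            h.center + ts.dhs_halfwidth,
            name="dhs_planted",
        )
        for h in promoter_like
    ]
    dhs += [
        GenomicInterval(iv.chrom, iv.start, iv.end, name="dhs_decoy")
        for iv in _random_intervals_avoiding(
            rng, config.chrom_lengths, ts.dhs_decoys, ts.dhs_decoy_width, planted, ts.planted_margin
        )
    ]

    chip = []
    for h in promoter_like:
        for j, label in enumerate(ts.chip_labels):
            pad = 60 + 10 * j
            chip.append(
                GenomicInterval(h.chrom, max(0, h.center - pad), h.center + pad, name=label)
            )
    decoy_labels = [f"TF_decoy_{i % 7}" for i in range(ts.chip_decoys)]
    for iv, label in zip(
        _random_intervals_avoiding(
            rng, config.chrom_lengths, ts.chip_decoys, ts.chip_decoy_width, planted, ts.planted_margin
        ),
        decoy_labels,
    ):
        chip.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=label))

    blacklist = _random_intervals_avoiding(
        rng, config.chrom_lengths, ts.blacklist_n, ts.blacklist_width, planted, ts.planted_margin
    )

    def _mappable(gaps: list[GenomicInterval]) -> list[GenomicInterval]:
        out = []
        by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in config.chrom_lengths}
        for g in gaps:
            by_chrom[g.chrom].append(g)
        for chrom in sorted(config.chrom_lengths):
            L = config.chrom_lengths[chrom]
            cur = 0
            for g in sorted(by_chrom[chrom], key=lambda g: g.start):
                if g.start > cur:
                    out.append(GenomicInterval(chrom, cur, g.start, score=1.0))
                out.append(GenomicInterval(chrom, g.start, g.end, score=0.0))
                cur = g.end
            if cur < L:
                out.append(GenomicInterval(chrom, cur, L, score=1.0))
        return out

    gaps100 = _random_intervals_avoiding(
        rng, config.chrom_lengths, ts.map_gap_n, ts.map_gap_width, planted, ts.planted_margin
    )
    gaps20 = _random_intervals_avoiding(
        rng, config.chrom_lengths, ts.map_gap_n, ts.map_gap_width, planted, ts.planted_margin
    )

    state = [
        GenomicInterval(h.chrom, max(0, h.start - 500), h.end + 500, name="Active_TSS")
        for h in promoter_like
    ]

    return TrackSet(
        {
            "dhs": dhs,
            "chip": chip,
            "blacklist": blacklist,
            "mappable100": _mappable(gaps100),
            "mappable20": _mappable(gaps20),
            "state": state,
        }
    )
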