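"""UV mutational-signature classification.

Ultraviolet photoproducts (cyclobutane pyrimidine dimers and 6-4
photoproducts) form at dipyrimidines, so the diagnostic UV spectrum is C→T
transitions with an adjacent pyrimidine on the strand carrying the mutated
cytosine — observed as C→T next to a C or T, or, when the lesion sits on the
minus strand, G→A next to a G or A — with a minority of tandem CC→TT
(GG→AA) dinucleotide changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import (
    Cohort,
    GenomicInterval,
    PYRIMIDINES,
    PURINES,
    ReferenceSequence,
    SnvRecord,
    positions_in_intervals,
)


@dataclass
class DinucPair:
    """A same-sample tandem CC→TT or GG→AA event at (pos, pos + 1)."""

    sample_id: str
    chrom: str
    pos: int  # 1-based position of the 5' member
    ref_dinuc: str  # "CC" or "GG"


@dataclass
class SpectrumSummary:
    """Cohort mutation-spectrum summary.

    Record-level counts (``n_total``, ``n_uv``, ``n_unknown``) count every
    SNV row; ``n_dinuc_events`` counts tandem pairs once.  The reported
    fractions are per mutational *event* — a tandem dinucleotide, arising
    from a single photoproduct, contributes one event — so
    ``uv_fraction = (n_uv - n_dinuc) / (n_total - n_dinuc)`` and
    ``dinuc_fraction_of_uv = n_dinuc / (n_uv - n_dinuc)``.  Unknown-context
    SNVs (N bases) are excluded from all denominators.
    """

    n_total: int
    n_uv: int
    n_unknown: int
    n_dinuc_events: int
    uv_fraction: float | None
    dinuc_fraction_of_uv: float | None
    substitution_table: pd.DataFrame
    dinuc_pairs: list[DinucPair] = field(default_factory=list)


def classify_uv(snv: SnvRecord, ref: ReferenceSequence) -> str:
    """Classify one SNV as ``uv``, ``non_uv`` or ``unknown``.

    ``uv``: C→T with a pyrimidine neighbour on the plus strand, or G→A with
    a purine neighbour (the strand-mirrored dipyrimidine).  ``unknown``: the
    site or a needed neighbour is N.
    """
    if snv.chrom not in ref:
        raise KeyError(f"chromosome {snv.chrom!r} not in reference")
    if not (1 <= snv.pos <= ref.length(snv.chrom)):
        raise IndexError(f"position {snv.chrom}:{snv.pos} outside reference")
    left, base, right = ref.context(snv.chrom, snv.pos)
    if base == "N":
        return "unknown"
    if base != snv.ref:
        raise ValueError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: ref has {base}, SNV claims {snv.ref}"
        )
    if (snv.ref, snv.alt) == ("C", "T"):
        if left == "N" and right == "N":
            return "unknown"
        if left in PYRIMIDINES or right in PYRIMIDINES:
            return "uv"
        if "N" in (left, right):
            return "unknown"
        return "non_uv"
    if (snv.ref, snv.alt) == ("G", "A"):
        if left == "N" and right == "N":
            return "unknown"
        if left in PURINES or right in PURINES:
            return "uv"
        if "N" in (left, right):
            return "unknown"
        return "non_uv"
    return "non_uv"


def detect_dinucleotides(cohort: Cohort, ref: ReferenceSequence) -> list[DinucPair]:
    """Tandem CC→TT / GG→AA pairs: same sample, adjacent positions, matching
    substitutions on a CC (or GG) reference run.

    Runs of three or more adjacent qualifying SNVs are paired greedily left
    to right; each SNV joins at most one pair.
    """
    pairs: list[DinucPair] = []
    df = cohort.df
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=True):
        pos = grp["pos"].to_numpy()
        refs = grp["ref"].to_numpy()
        alts = grp["alt"].to_numpy()
        i = 0
        while i < len(pos) - 1:
            if (
                pos[i + 1] == pos[i] + 1
                and (
                    (refs[i] == "C" and alts[i] == "T" and refs[i + 1] == "C" and alts[i + 1] == "T")
                    or (refs[i] == "G" and alts[i] == "A" and refs[i + 1] == "G" and alts[i + 1] == "A")
                )
                and ref.slice(chrom, pos[i] - 1, pos[i] + 1) == refs[i] + refs[i]
            ):
                pairs.append(DinucPair(sample, chrom, int(pos[i]), refs[i] * 2))
                i += 2  # greedy: members join at most one pair
            else:
                i += 1
    return pairs


def summarize_spectrum(
    cohort: Cohort,
    ref: ReferenceSequence,
    subset: Sequence[GenomicInterval] | None = None,
) -> SpectrumSummary:
    """Spectrum summary, optionally restricted to SNVs inside ``subset``
    intervals (e.g. hotspot regions)."""
    sub = cohort
    if subset is not None:
        if len(cohort) == 0:
            mask = []
        else:
            mask = positions_in_intervals(
                cohort.df["chrom"].tolist(), cohort.df["pos"].to_numpy(), list(subset)
            )
        sub = cohort.subset_positions(mask)

    n_uv = n_unknown = 0
    table: dict[tuple[str, str, str], int] = {}
    for snv in sub.records():
        cls = classify_uv(snv, ref)
        if cls == "uv":
            n_uv += 1
        elif cls == "unknown":
            n_unknown += 1
        key = (snv.ref, snv.alt, cls)
        table[key] = table.get(key, 0) + 1
    pairs = detect_dinucleotides(sub, ref)
    n_dinuc = len(pairs)
    n_known = len(sub) - n_unknown
    n_events = n_known - n_dinuc  # tandem pair = one event
    uv_events = n_uv - n_dinuc
    uv_fraction = uv_events / n_events if n_events > 0 else None
    dinuc_fraction = n_dinuc / uv_events if uv_events > 0 else None
    table_df = pd.DataFrame(
        [(r, a, c, n) for (r, a, c), n in sorted(table.items())],
        columns=["ref", "alt", "classification", "count"],
    )
    return SpectrumSummary(
        n_total=len(sub),
        n_uv=n_uv,
        n_unknown=n_unknown,
        n_dinuc_events=n_dinuc,
        uv_fraction=uv_fraction,
        dinuc_fraction_of_uv=dinuc_fraction,
        substitution_table=table_df,
        dinuc_pairs=pairs,
    )
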