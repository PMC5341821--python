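"""Panel-call filtering, promoter mutation load, and association testing.

Covers the downstream reporting stages: stringent filtering of multiplex
amplicon-panel calls (depth, duplicate concordance, allelic fraction,
discovery-set whitelist), per-sample promoter mutation load, nonparametric
association tests against clinicopathologic covariates, load-vs-load
regression, per-gene expression-by-mutation tests with FDR correction, and
strand-aware mapping of SNVs onto transcription-factor motif positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import COMPLEMENT, Cohort, GenomicInterval
from .stats import bh_qvalues


@dataclass
class PanelCall:
    """One candidate SNV from the duplicate amplicon panel.

    ``replicates`` holds one ``(depth, alt_fraction)`` tuple per replicate in
    which the variant was called (one or two entries).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    replicates: tuple[tuple[int, float], ...]
    in_whitelist: bool = False

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("a panel call needs at least one replicate observation")


@dataclass
class SampleLoad:
    sample_id: str
    promoter_mutation_load: int
    covariates: dict = field(default_factory=dict)
    nonsynonymous_load: int | None = None


def filter_panel_calls(
    calls: Sequence[PanelCall], min_depth: int = 50, min_af: float = 0.1
) -> list[PanelCall]:
    """High-stringency panel calls.

    A call is retained iff all of:
    1. read depth > ``min_depth`` in every replicate supporting the call;
    2. the variant is present in both replicates, or in a single replicate
       with allelic fraction > ``min_af``;
    3. the position is whitelisted (present in the discovery-set mutations).
    """
    kept = []
    for call in calls:
        if not call.in_whitelist:
            continue
        if any(depth <= min_depth for depth, _ in call.replicates):
            continue
        if len(call.replicates) >= 2:
            kept.append(call)
        elif call.replicates[0][1] > min_af:
            kept.append(call)
    return kept


def sample_exclusion(
    amplicon_read_counts: pd.DataFrame,
    max_low_either: int = 30,
    max_low_both: int = 20,
    min_reads: int = 100,
) -> list[str]:
    """Samples passing amplicon coverage QC.

    A sample is excluded if more than ``max_low_either`` amplicons have fewer
    than ``min_reads`` reads in either duplicate, or if both duplicates have
    more than ``max_low_both`` such amplicons.  Input columns:
    ``sample, amplicon, reads_rep1, reads_rep2``.
    """
    required = {"sample", "amplicon", "reads_rep1", "reads_rep2"}
    if not required.issubset(amplicon_read_counts.columns):
        raise ValueError(f"need columns {sorted(required)}")
    kept = []
    for sample, grp in amplicon_read_counts.groupby("sample", sort=True):
        low1 = int((grp["reads_rep1"] < min_reads).sum())
        low2 = int((grp["reads_rep2"] < min_reads).sum())
        if low1 > max_low_either or low2 > max_low_either:
            continue
        if low1 > max_low_both and low2 > max_low_both:
            continue
        kept.append(sample)
    return kept


def compute_loads(
    calls: Sequence[PanelCall],
    covariates: pd.DataFrame | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[SampleLoad]:
    """Per-sample promoter mutation load: the count of retained calls.

    ``covariates`` (indexed by or containing a ``sample`` column) is joined
    by sample id; samples present only in ``sample_ids``/covariates get load
    zero.
    """
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.sample_id] = counts.get(call.sample_id, 0) + 1
    cov_map: dict[str, dict] = {}
    if covariates is not None:
        cov = covariates.copy()
        if "sample" in cov.columns:
            cov = cov.set_index("sample")
        cov_map = {str(ix): row.dropna().to_dict() for ix, row in cov.iterrows()}
    samples = set(counts) | set(cov_map)
    if sample_ids is not None:
        samples |= set(sample_ids)
    loads = []
    for s in sorted(samples):
        cov_row = dict(cov_map.get(s, {}))
        nonsyn = cov_row.pop("nonsynonymous_load", None)
        loads.append(
            SampleLoad(
                sample_id=s,
                promoter_mutation_load=counts.get(s, 0),
                covariates=cov_row,
                nonsynonymous_load=None if nonsyn is None else int(nonsyn),
            )
        )
    return loads


@dataclass
class AssociationResult:
    covariate: str
    test: str  # mann_whitney | kruskal_wallis | spearman | no_variance
    statistic: float | None
    p_value: float | None
    group_sizes: dict
    estimate: float | None = None  # Spearman rho when numeric


def association_tests(
    loads: Sequence[SampleLoad], covariate: str, numeric: bool = False
) -> AssociationResult:
    """Nonparametric association of promoter mutation load with a covariate.

    Two-level covariates get a two-sided Mann-Whitney U, multi-level ones a
    Kruskal-Wallis test, and numeric covariates a Spearman correlation.
    Samples missing the covariate are excluded pairwise.
    """
    pairs = [
        (l.promoter_mutation_load, l.covariates[covariate])
        for l in loads
        if covariate in l.covariates and not pd.isna(l.covariates[covariate])
    ]
    if not pairs:
        raise ValueError(f"no samples carry covariate {covariate!r}")
    values = np.array([v for v, _ in pairs], dtype=float)
    labels = [g for _, g in pairs]

    if numeric:
        x = np.asarray(labels, dtype=float)
        if np.ptp(values) == 0 or np.ptp(x) == 0:
            return AssociationResult(covariate, "no_variance", None, None, {"n": len(values)})
        rho, p = sps.spearmanr(x, values)
        return AssociationResult(
            covariate, "spearman", float(rho), float(p), {"n": len(values)}, estimate=float(rho)
        )

    groups: dict = {}
    for v, g in zip(values, labels):
        groups.setdefault(g, []).append(v)
    sizes = {g: len(vs) for g, vs in sorted(groups.items(), key=lambda kv: str(kv[0]))}
    empty = [g for g, n in sizes.items() if n == 0]
    if empty:
        raise ValueError(f"empty group(s) after exclusions: {empty}")
    if len(groups) < 2:
        raise ValueError(f"covariate {covariate!r} has a single level")
    if np.ptp(values) == 0:
        return AssociationResult(covariate, "no_variance", None, None, sizes)
    if len(groups) == 2:
        (a, b) = (np.array(v) for v in groups.values())
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return AssociationResult(covariate, "mann_whitney", float(stat), float(p), sizes)
    stat, p = sps.kruskal(*groups.values())
    return AssociationResult(covariate, "kruskal_wallis", float(stat), float(p), sizes)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    n: int


def regress_loads(loads: Sequence[SampleLoad]) -> RegressionResult:
    """OLS of promoter mutation load on non-synonymous mutation load."""
    import statsmodels.api as sm

    pts = [
        (l.nonsynonymous_load, l.promoter_mutation_load)
        for l in loads
        if l.nonsynonymous_load is not None
    ]
    if len(pts) < 3:
        raise ValueError("need >= 3 samples with both loads")
    x = np.array([a for a, _ in pts], dtype=float)
    y = np.array([b for _, b in pts], dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_p=float(fit.pvalues[1]),
        n=len(pts),
    )


def test_expression_by_mutation(
    expression: pd.DataFrame, mutation_status: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Mann-Whitney U of expression by promoter-mutation status.

    ``expression``: samples x genes; ``mutation_status``: same shape,
    boolean.  Genes without at least one mutated and one wild-type sample
    are excluded (returned in the second element).  q-values are BH across
    the tested genes.
    """
    if not expression.index.equals(mutation_status.index):
        mutation_status = mutation_status.reindex(expression.index)
    rows, excluded = [], []
    for gene in expression.columns:
        if gene not in mutation_status.columns:
            excluded.append(gene)
            continue
        status = mutation_status[gene].astype(bool)
        expr = expression[gene]
        ok = expr.notna() & status.notna()
        mut = expr[ok & status]
        wt = expr[ok & ~status]
        if len(mut) == 0 or len(wt) == 0:
            excluded.append(gene)
            continue
        stat, p = sps.mannwhitneyu(mut, wt, alternative="two-sided")
        rows.append((gene, len(mut), len(wt), float(stat), float(p)))
    result = pd.DataFrame(rows, columns=["gene", "n_mutated", "n_wildtype", "U", "p_value"])
    if len(result):
        result["q_value"] = bh_qvalues(result["p_value"].to_numpy())
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result, excluded


def map_snvs_to_motif(
    cohort: Cohort,
    motif_occurrences: Sequence[GenomicInterval],
    motif_length: int,
) -> pd.DataFrame:
    """Assign SNVs inside motif occurrences to 1-based motif positions.

    Positions count from the motif's 5' end; for minus-strand occurrences
    the position is reversed and ref/alt complemented, so counts are always
    reported on the motif strand.  Output columns:
    ``position, ref, alt, count``.
    """
    counts: dict[tuple[int, str, str], int] = {}
    for occ in motif_occurrences:
        if occ.width != motif_length:
            raise ValueError(
                f"occurrence {occ.chrom}:{occ.start}-{occ.end} width {occ.width} != motif length {motif_length}"
            )
        if occ.strand not in ("+", "-"):
            raise ValueError("motif occurrences must be stranded")
        sel = cohort.df[
            (cohort.df["chrom"] == occ.chrom)
            & (cohort.df["pos"] - 1 >= occ.start)
            & (cohort.df["pos"] - 1 < occ.end)
        ]
        for row in sel.itertuples(index=False):
            offset = int(row.pos) - 1 - occ.start  # 0-based within occurrence
            if occ.strand == "+":
                key = (offset + 1, row.ref, row.alt)
            else:
                key = (motif_length - offset, COMPLEMENT[row.ref], COMPLEMENT[row.alt])
            counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [(p, r, a, n) for (p, r, a), n in sorted(counts.items())],
        columns=["position", "ref", "alt", "count"],
    )
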