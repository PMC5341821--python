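import numpy as np
import pandas as pd
import pytest

from uvhotspots.core import Cohort, GenomicInterval, ReferenceSequence


def make_cohort(events, genome_length=3_000_000_000, sample_ids=None):
    """Cohort from (sample, chrom, pos[, ref, alt]) tuples (pos 1-based)."""
    rows = []
    for ev in events:
        if len(ev) == 3:
            s, c, p = ev
            r, a = "A", "C"
        else:
            s, c, p, r, a = ev
        rows.append((s, c, p, r, a, np.nan, np.nan))
    df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_fraction"]
    )
    return Cohort(df, sample_ids=sample_ids, genome_length=genome_length)


def random_cohort(rng, n_snvs, chrom_len, n_samples=10, chrom="1"):
    samples = [f"S{i}" for i in range(n_samples)]
    events = []
    seen = set()
    while len(events) < n_snvs:
        s = samples[int(rng.integers(n_samples))]
        p = int(rng.integers(1, chrom_len + 1))
        if (s, p) in seen:
            continue
        seen.add((s, p))
        events.append((s, chrom, p))
    return make_cohort(events, genome_length=chrom_len)


@pytest.fixture
def tiny_ref():
    #            123456789012345678
    return ReferenceSequence({"1": "ATCAGGCCATTACGTACG", "2": "GGGGAAAACCCCTTTT"})


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
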