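"""Shared independent oracles used by several test modules."""

from math import comb


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of the hypergeometric
    support at fixed margins (minimum-likelihood tail definition)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


import numpy as np

from rbpatlas.annotation import RepeatFamilyDB, RepeatTranscript
from rbpatlas.reads import ReadRecord


def make_repeat_db():
    return RepeatFamilyDB(
        [
            RepeatTranscript("RNA18S", "rRNA18S", 1, 1869),
            RepeatTranscript("RNA18SP1", "rRNA18S", 7, 1800),
            RepeatTranscript("AluYa5", "Alu", 1, 300),
            RepeatTranscript("L1HS", "L1", 1, 6000),
            RepeatTranscript("SR_AC", "simple repeat", 1, 60),
        ],
        simple_repeat_families={"simple repeat"},
    )


def rec(read_id, target, mism=0, strand="+", start=0, stop=50,
        umi="ACGTACGTAC", score=0):
    return ReadRecord(read_id, umi, start, stop, strand, target, score, mism)


def random_records(rng, n, umis=4, positions=8):
    out = []
    for i in range(n):
        start = int(rng.integers(0, positions)) * 10
        out.append(
            ReadRecord(
                read_id=f"r{i:05d}",
                umi="ACGTACGTA" + str(rng.integers(0, umis)),
                start=start,
                stop=start + 50,
                target="chrS",
            )
        )
    return out
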