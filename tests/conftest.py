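import random

import pytest

from alnviz.model import AlignmentRecord, AlignmentSet, Strand


def make_record(
    query_name="q1",
    query_length=1000,
    query_start=0,
    query_end=480,
    target_name="T1",
    target_length=5000,
    target_start=100,
    target_end=590,
    strand=Strand.FORWARD,
    **kwargs,
):
    return AlignmentRecord(
        query_name=query_name,
        query_length=query_length,
        query_start=query_start,
        query_end=query_end,
        target_name=target_name,
        target_length=target_length,
        target_start=target_start,
        target_end=target_end,
        strand=strand,
        **kwargs,
    )


def random_record(rng: random.Random, queries=("a", "b", "c"),
                  targets={"T1": 50_000, "T2": 30_000}):
    qlen = rng.randint(100, 10_000)
    qs = rng.randint(0, qlen - 2)
    qe = rng.randint(qs + 1, qlen)
    target_name = rng.choice(list(targets))
    tlen = targets[target_name]
    ts = rng.randint(0, tlen - 2)
    te = rng.randint(ts + 1, tlen)
    return AlignmentRecord(
        query_name=rng.choice(list(queries)),
        query_length=qlen,
        query_start=qs,
        query_end=qe,
        target_name=target_name,
        target_length=tlen,
        target_start=ts,
        target_end=te,
        strand=rng.choice((Strand.FORWARD, Strand.REVERSE)),
    )


@pytest.fixture
def rng():
    return random.Random(20240101)


@pytest.fixture
def random_set(rng):
    return AlignmentSet(random_record(rng) for _ in range(100))
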