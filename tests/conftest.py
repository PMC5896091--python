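import numpy as np
import pytest

from apokat.catalog import SNVRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_record(
    pos,
    ref="C",
    alt="T",
    context5="T",
    context3="A",
    chrom="chr1",
    cell_line="CL",
    pop_af=None,
):
    return SNVRecord(
        cell_line_id=cell_line,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        context5=context5,
        context3=context3,
        pop_af=pop_af,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_catalog(rng, n, cell_line="CL", chroms=("chr1",), max_pos=100_000):
    """Random SNV records with random substitutions and contexts."""
    bases = "ACGT"
    records = []
    used = set()
    while len(records) < n:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(2, max_pos))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        if alt == ref:
            continue
        records.append(
            SNVRecord(
                cell_line_id=cell_line,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                context5=bases[rng.integers(4)],
                context3=bases[rng.integers(4)],
                pop_af=float(rng.uniform(0, 0.2)) if rng.random() < 0.3 else None,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


@pytest.fixture
def catalog_factory():
    return random_catalog
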