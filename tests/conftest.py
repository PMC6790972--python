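import numpy as np
import pandas as pd
import pytest

from nitriflux.compgen import HIT_COLUMNS


def make_hit(query, subject, identity, align_length, bitscore,
             query_length=None, subject_length=None):
    qlen = query_length if query_length is not None else align_length
    slen = subject_length if subject_length is not None else align_length
    return dict(
        query=query, subject=subject, identity=identity,
        align_length=align_length, mismatches=0, gap_opens=0,
        qstart=1, qend=align_length, sstart=1, send=align_length,
        evalue=1e-30, bitscore=bitscore,
        query_length=qlen, subject_length=slen,
    )


def hit_frame(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


@pytest.fixture
def reciprocal_hits():
    """Three clean reciprocal pairs: identities 50/60/70, lengths 100/200/300."""
    fwd, rev = [], []
    for i, (ident, length) in enumerate([(50.0, 100), (60.0, 200), (70.0, 300)]):
        fwd.append(make_hit(f"a{i}", f"b{i}", ident, length, bitscore=2.0 * length))
        rev.append(make_hit(f"b{i}", f"a{i}", ident, length, bitscore=2.0 * length))
    return hit_frame(fwd), hit_frame(rev)


def random_hit_tables(rng, n_a=8, n_b=8, n_hits=30):
    """Random directed hit tables over small gene sets for oracle checks."""
    qlen_a = {f"a{i}": int(rng.integers(80, 400)) for i in range(n_a)}
    qlen_b = {f"b{i}": int(rng.integers(80, 400)) for i in range(n_b)}

    def table(queries, subjects):
        rows = []
        for _ in range(n_hits):
            q = rng.choice(list(queries))
            s = rng.choice(list(subjects))
            alen = int(queries[q] * rng.uniform(0.4, 1.0))
            rows.append(make_hit(
                q, s, float(rng.uniform(30, 100)), alen,
                bitscore=float(rng.uniform(50, 500)),
                query_length=queries[q], subject_length=subjects[s],
            ))
        return hit_frame(rows)

    return table(qlen_a, qlen_b), table(qlen_b, qlen_a)
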