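import numpy as np
import pytest

from passagefit import copynum as cn


def random_seq(n, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def te_fixture():
    """Synthetic TE consensus pair (Tf2 plus a ~15%-diverged Tf1), a
    single-copy panel, and a builder for genomes carrying c Tf2 copies."""
    rng = np.random.default_rng(42)
    tf2 = random_seq(945, rng)
    tf1 = list(tf2)
    for i in rng.choice(945, size=140, replace=False):
        tf1[i] = rng.choice([b for b in "ACGT" if b != tf1[i]])
    tf1 = "".join(tf1)
    panel = [(f"gene{i}", random_seq(1000, rng)) for i in range(8)]
    background = random_seq(20000, rng)

    def make_genome(c):
        spacer = background[10000:10200]
        return (
            "".join(s for _, s in panel)
            + background[:10000]
            + (tf2 + spacer) * c
            + background[10200:]
        )

    def make_reads(genome, coverage=30, read_len=100, seed=7):
        r = np.random.default_rng(seed)
        n_reads = int(len(genome) * coverage / read_len)
        starts = r.integers(0, len(genome) - read_len, size=n_reads)
        return [(f"r{i}", genome[s : s + read_len]) for i, s in enumerate(starts)]

    return {
        "tf2": tf2,
        "tf1": tf1,
        "panel": panel,
        "make_genome": make_genome,
        "make_reads": make_reads,
        "region": cn.ConsensusRegion("Tf2", tf2),
        "rng": rng,
    }


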