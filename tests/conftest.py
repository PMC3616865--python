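import numpy as np
import pandas as pd
import pytest

from phylostrat import synthetic
from phylostrat.lineage import fish_lineage, mouse_lineage


@pytest.fixture(scope="session")
def mouse_map():
    return mouse_lineage()


@pytest.fixture(scope="session")
def fish_map():
    return fish_lineage()


@pytest.fixture(scope="session")
def noise_free_dataset():
    return synthetic.generate_dataset(synthetic.noise_free_preset())


@pytest.fixture(scope="session")
def paper_like_dataset():
    return synthetic.generate_dataset(synthetic.paper_like_preset())


def make_gene_table(
    rng: np.random.Generator,
    n_strata: int = 5,
    genes_per_stratum: int = 40,
    n_chromosomes: int = 2,
) -> pd.DataFrame:
    """Small featureless gene table for statistics tests (no trends)."""
    n = n_strata * genes_per_stratum
    strata = np.repeat(np.arange(1, n_strata + 1), genes_per_stratum)
    gene_length = rng.integers(2_000, 40_000, size=n)
    orf_length = np.minimum(rng.integers(300, 1_800, size=n), gene_length)
    return pd.DataFrame(
        {
            "id": [f"G{i:05d}" for i in range(n)],
            "stratum": strata,
            "chromosome": rng.choice(
                [f"chr{i + 1}" for i in range(n_chromosomes)], size=n
            ),
            "strand": rng.choice(["+", "-"], size=n),
            "tss": rng.integers(0, 5_000_000, size=n),
            "gene_length": gene_length,
            "orf_length": orf_length,
            "exon_count": rng.integers(1, 12, size=n),
            "mean_exon_length": np.minimum(
                rng.integers(80, 400, size=n), gene_length
            ),
            "domain_count": rng.integers(0, 5, size=n),
        }
    )


# ---------------------------------------------------------------------------
# Independent alignment oracle: recursive maximization over every alignment
# extension (diagonal / gap-in-b / gap-in-a), memoized on (i, j, last move).
# Gap model matches the package's convention: the first column of a gap run
# scores gap_open, each further column gap_extend; global alignments pay for
# end gaps.
# ---------------------------------------------------------------------------

def oracle_global_score(a, b, match, mismatch, gap_open, gap_extend):
    from functools import lru_cache

    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == la and j == lb:
            return 0.0
        options = []
        if i < la and j < lb:
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, 0))
        if i < la:
            g = gap_extend if state == 1 else gap_open
            options.append(g + best(i + 1, j, 1))
        if j < lb:
            g = gap_extend if state == 2 else gap_open
            options.append(g + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


def oracle_local_score(a, b, match, mismatch, gap_open, gap_extend):
    """Best global score over all substring pairs, floored at zero."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    score = oracle_global_score(
                        a[i0:i1], b[j0:j1], match, mismatch, gap_open, gap_extend
                    )
                    best = max(best, score)
    return best


def enumerate_alignment_scores(a, b, match, mismatch, gap_open, gap_extend):
    """Yield the score of every distinct global alignment (no memoization).

    Used only on tiny inputs to validate the recursive oracle itself.
    """
    la, lb = len(a), len(b)

    def walk(i, j, state, acc):
        if i == la and j == lb:
            yield acc
            return
        if i < la and j < lb:
            s = match if a[i] == b[j] else mismatch
            yield from walk(i + 1, j + 1, 0, acc + s)
        if i < la:
            g = gap_extend if state == 1 else gap_open
            yield from walk(i + 1, j, 1, acc + g)
        if j < lb:
            g = gap_extend if state == 2 else gap_open
            yield from walk(i, j + 1, 2, acc + g)

    yield from walk(0, 0, 0, 0.0)
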