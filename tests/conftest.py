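import itertools

import numpy as np
import pytest

from segcond import fixtures, make_grid, run_pipeline


@pytest.fixture(scope="session")
def small_grid():
    return make_grid({"chr1": 50_000, "chr2": 23_000}, 5_000)


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.default_fixture_spec(seed=0)


@pytest.fixture(scope="session")
def default_run(default_spec):
    """Full pipeline on the default planted fixture (shared across tests)."""
    matrix = fixtures.generate_tracks(default_spec)
    contacts = fixtures.generate_contacts(default_spec)
    return run_pipeline(matrix, contacts, n_shuffles=1000, n_perm=100, seed=0)


def exhaustive_breakpoints(signal, min_seg, max_breaks):
    """Independent oracle: enumerate every admissible break placement.

    Minimizes RSS per break count m (positions compared lexicographically on
    ties), then selects m by BIC(m) = n ln(RSS/n) + (2m + 2) ln(n), smallest
    m on ties.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size

    def rss(edges):
        tot = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = x[a:b]
            tot += float(np.sum((seg - seg.mean()) ** 2))
        return tot

    best = {}
    for m in range(max_breaks + 1):
        best_rss, best_brk = np.inf, None
        for brk in itertools.combinations(range(n - 1), m):
            edges = [0] + [b + 1 for b in brk] + [n]
            if any(e - a < min_seg for a, e in zip(edges[:-1], edges[1:])):
                continue
            r = rss(edges)
            if r < best_rss:
                best_rss, best_brk = r, list(brk)
        if best_brk is not None:
            best[m] = (best_rss, best_brk)

    def bic(m, r):
        term = np.log(r / n) if r > 0 else -np.inf
        return n * term + (2 * m + 2) * np.log(n)

    m_star = min(best, key=lambda m: (bic(m, best[m][0]), m))
    return best[m_star][1]
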