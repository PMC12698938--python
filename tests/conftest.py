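import numpy as np
import pytest

from uniroc import EvalDataset, table1, table1_tied, table1_weights


@pytest.fixture
def t1():
    return table1()


@pytest.fixture
def t1_weights():
    return table1_weights()


@pytest.fixture
def t1_tied():
    return table1_tied()


@pytest.fixture
def toy_perfect():
    return EvalDataset([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])


def pair_auc(hs, sp, w=None):
    """O(n^2) pair-enumeration AUC oracle: concordant presence-absence
    pairs (ties count one half), weighted by the product of case weights."""
    hs = np.asarray(hs, float)
    sp = np.asarray(sp)
    w = np.ones_like(hs) if w is None else np.asarray(w, float)
    num = den = 0.0
    for i in np.flatnonzero(sp == 1):
        for j in np.flatnonzero(sp == 0):
            wij = w[i] * w[j]
            den += wij
            if hs[i] > hs[j]:
                num += wij
            elif hs[i] == hs[j]:
                num += 0.5 * wij
    return num / den


def brute_se_star(hs, sp, w=None):
    """Exhaustive Se* oracle: evaluate Se and Sp at every threshold
    (each unique score, plus 'call nothing present') by direct summation."""
    hs = np.asarray(hs, float)
    sp = np.asarray(sp)
    w = np.ones_like(hs) if w is None else np.asarray(w, float)
    tot_p = w[sp == 1].sum()
    tot_a = w[sp == 0].sum()
    best = None
    for t in list(np.unique(hs)) + [np.inf]:
        se = w[(sp == 1) & (hs >= t)].sum() / tot_p
        spc = w[(sp == 0) & (hs < t)].sum() / tot_a
        key = (-abs(se - spc), (se + spc) / 2)
        if best is None or key > best[0]:
            best = (key, (se + spc) / 2, t)
    return best[1], best[2]


def random_dataset(rng, n_max=50, with_ties=True, weighted=False):
    """A random valid dataset, optionally with injected score ties."""
    while True:
        n = rng.integers(4, n_max + 1)
        if with_ties and rng.random() < 0.7:
            levels = rng.integers(2, max(3, n // 2) + 1)
            hs = rng.choice(np.round(rng.random(levels), 3), size=n)
        else:
            hs = rng.random(n)
        sp = rng.integers(0, 2, size=n)
        if 0 < sp.sum() < n:
            w = rng.uniform(0.05, 5.0, size=n) if weighted else None
            return EvalDataset(hs, sp, w)
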