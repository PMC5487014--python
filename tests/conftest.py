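"""Shared fixtures and the independent brute-force scoring oracle.

The oracle recomputes the seven-equation scoring chain with straight-line
loops over plain dictionaries, sharing no code with the package's vectorized
implementation, so agreement between the two is a meaningful check.
"""

import numpy as np
import pandas as pd
import pytest

from dataplan.scoring import DynamicModel, FactorSolution, ItemModuleMatrix, ItemStats


# ---------------------------------------------------------------------------
# brute-force oracle over plain dicts
# ---------------------------------------------------------------------------


def oracle_scores(factors, items, modules, pct, paths, loadings, means, matrix):
    """Straight-line recomputation of the full scoring chain.

    ``paths`` maps (source, target) -> beta for *retained* paths only;
    ``loadings`` maps (item, factor) -> loading for present loadings only;
    ``matrix`` maps (item, module) -> 0/1.
    """
    n = len(factors)
    raw_fs = {}
    for f in factors:
        dyn = 0.0
        for g in factors:
            if (f, g) in paths:
                dyn += paths[(f, g)] ** 2
        raw_fs[f] = pct[f] * dyn / n
    top = max(raw_fs.values())
    fsn = {f: (raw_fs[f] / top if top > 0 else 0.0) for f in factors}

    max_mean = max(means[i] for i in items)
    raw_is = {}
    for i in items:
        total = 0.0
        for f in factors:
            if (i, f) in loadings:
                total += fsn[f] * abs(loadings[(i, f)])
        raw_is[i] = (means[i] / max_mean) * total
    itop = max(raw_is.values())
    isn = {i: (raw_is[i] / itop if itop > 0 else 0.0) for i in items}

    raw_sum, item_avg = {}, {}
    for m in modules:
        matched = [i for i in items if matrix.get((i, m), 0) == 1]
        s = sum(isn[i] for i in matched)
        raw_sum[m] = s
        item_avg[m] = s / len(matched) if matched else 0.0
    amax = max(item_avg.values())
    smax = max(raw_sum.values())
    final = {
        m: (
            (item_avg[m] / amax if amax > 0 else 0.0)
            + (raw_sum[m] / smax if smax > 0 else 0.0)
        )
        / 2.0
        for m in modules
    }
    return {
        "raw_factor": raw_fs,
        "norm_factor": fsn,
        "raw_item": raw_is,
        "norm_item": isn,
        "item_avg": item_avg,
        "raw_sum": raw_sum,
        "final": final,
    }


def random_instance(rng, max_factors=5, max_items=15, max_modules=6):
    """Random small scoring instance in both dict (oracle) and object form."""
    k = rng.integers(1, max_factors + 1)
    p = rng.integers(k, max_items + 1)
    nm = rng.integers(1, max_modules + 1)
    factors = [f"F{i}" for i in range(k)]
    items = [f"item{i}" for i in range(p)]
    modules = list(range(2, 2 + nm))

    pct_vals = rng.uniform(0.02, 0.9, size=k)
    pct_vals = pct_vals / pct_vals.sum() * rng.uniform(0.3, 0.99)
    pct = dict(zip(factors, pct_vals))

    B = np.zeros((k, k))
    retained = np.zeros((k, k), dtype=bool)
    paths = {}
    for i in range(k):
        for j in range(k):
            if i == j or rng.random() < 0.4:
                beta = rng.uniform(-0.9, 0.9)
                B[i, j] = beta
                retained[i, j] = True
                paths[(factors[i], factors[j])] = beta

    lam = np.full((p, k), np.nan)
    loadings = {}
    for i in range(p):
        owned = rng.random(k) < 0.5
        if not owned.any() and rng.random() < 0.7:
            owned[rng.integers(k)] = True  # most items load somewhere
        for f in range(k):
            if owned[f]:
                val = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
                lam[i, f] = val
                loadings[(items[i], factors[f])] = val

    mean_vals = rng.uniform(1.0, 100.0, size=p)
    means = dict(zip(items, mean_vals))

    M = (rng.random((p, nm)) < 0.45).astype(int)
    matrix = {
        (items[i], modules[j]): int(M[i, j]) for i in range(p) for j in range(nm)
    }

    solution = FactorSolution(
        loadings=pd.DataFrame(lam, index=items, columns=factors),
        pct_variance=pd.Series(pct_vals, index=factors),
    )
    dyn = DynamicModel(
        paths=pd.DataFrame(B, index=factors, columns=factors),
        retained=pd.DataFrame(retained, index=factors, columns=factors),
    )
    stats = ItemStats(means=pd.Series(mean_vals, index=items))
    mm = ItemModuleMatrix(entries=pd.DataFrame(M, index=items, columns=modules))
    dicts = dict(
        factors=factors, items=items, modules=modules, pct=pct, paths=paths,
        loadings=loadings, means=means, matrix=matrix,
    )
    return solution, dyn, stats, mm, dicts


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def fixture021():
    from dataplan.synthetic import participant021_fixture

    return participant021_fixture()


@pytest.fixture
def matching_matrix():
    from dataplan.dataio import default_matrix

    return default_matrix()
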