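"""Independent reference implementations used only to check the library.

These deliberately avoid the code paths under test: compatibility is decided
by brute-force enumeration over the full haplotype space, and the maximum
likelihood is found by constrained numerical optimization over the frequency
simplex rather than EM.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize


def all_haplotypes(site_symbols):
    return list(itertools.product(*site_symbols))


def compatible_unordered_pairs(genotype, haplotypes):
    """All unordered haplotype pairs consistent with one unphased genotype."""
    pairs = []
    for i, h1 in enumerate(haplotypes):
        for h2 in haplotypes[i:]:
            ok = True
            for gt, a, b in zip(genotype, h1, h2):
                if gt is None:
                    continue
                if sorted((a, b)) != sorted(gt):
                    ok = False
                    break
            if ok:
                pairs.append((h1, h2))
    return pairs


def log_likelihood(freqs, genotypes, haplotypes):
    """Multinomial-sampling log likelihood of unphased genotypes."""
    index = {h: i for i, h in enumerate(haplotypes)}
    total = 0.0
    for g in genotypes:
        acc = 0.0
        for h1, h2 in compatible_unordered_pairs(g, haplotypes):
            f1, f2 = freqs[index[h1]], freqs[index[h2]]
            acc += f1 * f2 if h1 == h2 else 2 * f1 * f2
        if acc <= 0:
            return -math.inf
        total += math.log(acc)
    return total


def maximize_likelihood(genotypes, site_symbols, n_starts=8, seed=0):
    """Multi-start SLSQP maximization over the haplotype-frequency simplex.

    Returns (freq dict over haplotypes, max log likelihood).
    """
    haplotypes = all_haplotypes(site_symbols)
    H = len(haplotypes)
    rng = np.random.default_rng(seed)

    def neg_ll(x):
        return -log_likelihood(x, genotypes, haplotypes)

    best_x, best_ll = None, -math.inf
    starts = [np.full(H, 1.0 / H)] + [rng.dirichlet(np.ones(H)) for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(
            neg_ll, x0, method="SLSQP",
            bounds=[(0.0, 1.0)] * H,
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success and -res.fun > best_ll:
            best_ll = -res.fun
            best_x = res.x
    assert best_x is not None, "oracle optimizer failed on every start"
    return {h: f for h, f in zip(haplotypes, best_x)}, best_ll
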