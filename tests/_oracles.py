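"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain double
loops over set members and random sets, and a dense Riemann sum for the PT
AUC.  They are the oracles the optimized implementations are checked against.
"""

from __future__ import annotations

import numpy as np


def brute_mis(gene, target_members, network) -> int:
    """Max edge score between gene and any target member, excluding itself."""
    best = 0
    for member in target_members:
        if member == gene:
            continue
        s = network.score(gene, member)
        if s is not None and s > best:
            best = s
    return best


def brute_lambda(gene, query_mis, random_sets_members, network) -> int:
    """Exceedance count: #{i : MIS_i(gene) > query_mis}, strict comparison."""
    lam = 0
    for members in random_sets_members:
        if brute_mis(gene, members, network) > query_mis:
            lam += 1
    return lam


def riemann_pt_auc(p_values, n_steps: int = 1000) -> float:
    """Midpoint Riemann sum of t -> #{p < t}/n over [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    total = 0.0
    for k in range(n_steps):
        t = (k + 0.5) / n_steps
        total += np.count_nonzero(p < t) / p.size
    return total / n_steps
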