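"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force / direct formulas and
never call the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability is at most that of the observed table (with a tiny
    relative guard against floating-point ties).
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_group_enum(n: int, r1: int, c1: int) -> dict[int, float]:
    """Two-sided p for every table with margins (r1, n-r1) x (c1, n-c1)."""
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    out = {}
    for i, a in enumerate(support):
        out[int(a)] = float(pmf[pmf <= pmf[i] * (1 + 1e-7)].sum())
    return out


def bh_step_up(pvalues) -> list[float]:
    """Benjamini-Hochberg by the step-up formula, written out directly."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvalues[i] / rank)
        q[i] = running_min
    return q


def brute_contrasting_pairs(tree, geno: dict, pheno: dict) -> tuple[int, int, int]:
    """Exhaustive search for the maximum edge-disjoint contrasting pairing.

    A candidate pair differs in both genotype and phenotype; it supports
    when the genotype-1 tip is the phenotype-1 tip.  Returns
    (max_pairs, best_support, worst_support).
    """
    leaves = [
        l for l in tree.leaf_node_iter()
        if l.taxon and l.taxon.label in geno and l.taxon.label in pheno
    ]

    def root_path(node):
        out = []
        while node is not None:
            out.append(id(node))
            node = node.parent_node
        return out

    def path_edges(x, y):
        px, py = root_path(x), root_path(y)
        sx, sy = set(px), set(py)
        return frozenset(e for e in px if e not in sy) | frozenset(
            e for e in py if e not in sx
        )

    cand = []
    for x, y in itertools.combinations(leaves, 2):
        lx, ly = x.taxon.label, y.taxon.label
        if geno[lx] == geno[ly] or pheno[lx] == pheno[ly]:
            continue
        tip_one = lx if geno[lx] == 1 else ly
        support = 1 if pheno[tip_one] == 1 else 0
        cand.append((frozenset((id(x), id(y))), path_edges(x, y), support))

    best = {"m": 0, "smax": 0, "smin": 0}

    def rec(i, used_tips, used_edges, m, s):
        if m > best["m"]:
            best.update(m=m, smax=s, smin=s)
        elif m == best["m"]:
            best["smax"] = max(best["smax"], s)
            best["smin"] = min(best["smin"], s)
        for j in range(i, len(cand)):
            tips, edges, sup = cand[j]
            if tips & used_tips or edges & used_edges:
                continue
            rec(j + 1, used_tips | tips, used_edges | edges, m + 1, s + sup)

    rec(0, frozenset(), frozenset(), 0, 0)
    return best["m"], best["smax"], best["smin"]


def binom_upper_tail(k: int, n: int, p: float = 0.5) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )
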