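"""Association statistics: Fisher 2x2 machinery and the phylogeny-aware
contrasting-pairs test.

The Fisher odds ratio reported everywhere is the *unconditional sample*
odds ratio ``(a*d)/(b*c)`` with the degenerate-table conventions
``0/x = 0``, ``x/0 = +inf`` and ``0/0 = NA`` -- the form in which exact
zero (total depletion) and exact infinity (presence in every genome of a
genus) are meaningful summaries.  The two-sided p-value follows the
probability-at-most-observed rule (sum of hypergeometric probabilities of
all tables with the same margins that are no more probable than the one
observed).

The contrasting-pairs test (Read-Nee pairwise comparison, as popularised
by Scoary for pan-genome association) measures how many *phylogenetically
independent* examples of a genotype-phenotype association a rooted tree
contains.  A contrasting pair is a pair of tips that differ in genotype
and also differ in phenotype; pairs must not share tips and their
connecting paths must not share edges, so each pair witnesses a separate
evolutionary event.  A pair is *supporting* when the contrasts agree in
direction (the genotype-1 tip is the phenotype-1 tip) and *opposing*
otherwise; under the no-association null each contrasting pair supports
with probability 1/2, which is what makes the binomial reference
distribution exact.  Among all pairings of maximum total size, the best
and worst achievable numbers of supporting pairs are found by dynamic
programming, and each is converted to an upper-tail binomial probability
at success rate 1/2 over ``max_pairs`` trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import ParameterError

__all__ = [
    "ContingencyResult",
    "PairSummary",
    "sample_odds_ratio",
    "fisher_exact_2x2",
    "bh_adjust",
    "genus_enrichment",
    "max_contrasting_pairs",
]


@dataclass
class ContingencyResult:
    """A 2x2 table with sample odds ratio, Fisher p and BH q."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float  # may be 0.0, inf, or nan (0/0)
    p: float
    q: float | None = None


@dataclass
class PairSummary:
    """Contrasting-pairs result on one tree for one genotype/phenotype.

    ``max_pairs`` is the maximum number of tip-disjoint, path-edge-disjoint
    pairs contrasting in both traits; ``best_support``/``worst_support``
    bracket the supporting-pair count over all maximum pairings.
    """

    max_pairs: int
    best_support: int
    worst_support: int
    p_best: float  # nan when max_pairs == 0
    p_worst: float

    def __post_init__(self) -> None:
        assert 0 <= self.worst_support <= self.best_support <= self.max_pairs


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Unconditional sample OR with exact 0 / inf / NA sentinels."""
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        return float("nan")
    if bc == 0:
        return float("inf")
    return ad / bc


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample OR
    (see :func:`sample_odds_ratio`).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ParameterError(f"counts must be non-negative integers, got {v}")
    if a + b + c + d == 0:
        raise ParameterError("empty table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return sample_odds_ratio(a, b, c, d), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genus_enrichment(
    presence: Mapping[str, int] | pd.Series,
    taxonomy: Mapping[str, str],
    min_entries: int = 10,
    q_report: float = 0.001,
) -> pd.DataFrame:
    """Per-genus eCIS enrichment/depletion via Fisher + BH.

    ``presence`` maps genome -> 0/1 eCIS presence; ``taxonomy`` maps
    genome -> genus (genomes without a label count as "unclassified").
    Genomes in ``taxonomy`` missing from ``presence`` are skipped with a
    warning.  All genera are tested and BH-corrected together; the
    ``reportable`` flag marks rows with q < ``q_report`` and genus size
    >= ``min_entries``.
    """
    presence = pd.Series(dict(presence)) if not isinstance(presence, pd.Series) else presence
    genomes = list(presence.index)
    missing = [g for g in taxonomy if g not in presence.index]
    if missing:
        warnings.warn(
            f"{len(missing)} genome(s) in taxonomy absent from presence table, skipped"
        )
    genus_of = {g: taxonomy.get(g, "unclassified") for g in genomes}
    total_pos = int(presence.sum())
    total = len(genomes)
    rows = []
    for genus in sorted(set(genus_of.values())):
        members = [g for g in genomes if genus_of[g] == genus]
        a = int(sum(presence[g] for g in members))  # genus & eCIS+
        b = len(members) - a                        # genus & eCIS-
        c = total_pos - a                           # other & eCIS+
        d = (total - len(members)) - c              # other & eCIS-
        oratio, p = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {"genus": genus, "n_genomes": len(members), "a": a, "b": b, "c": c,
             "d": d, "odds_ratio": oratio, "p": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["reportable"] = (df["q"] < q_report) & (df["n_genomes"] >= min_entries)
    return df


# ---------------------------------------------------------------------------
# contrasting pairs
# ---------------------------------------------------------------------------

# A tip's joint state is (genotype, phenotype); a dangling tip of state
# (g, p) is one reserved for matching across the current node's parent
# edge.  Internal DP state per subtree: for "none" and for each dangle
# type, the maximum number of pairs and, over all configurations
# achieving it, the best and worst support count.

_DANGLES = ((1, 1), (1, 0), (0, 1), (0, 0))


def _match_stats(n11: int, n10: int, n01: int, n00: int) -> tuple[int, int, int]:
    """Maximum matching of dangle multisets across a node.

    A pair must contrast in both traits, so matching runs in two disjoint
    channels: (1,1)x(0,0) pairs support and (1,0)x(0,1) pairs oppose.
    Returns (pairs, support, support) -- the support of a maximum
    matching at a single node is forced; best/worst freedom arises from
    which dangles the children present.
    """
    s = min(n11, n00)
    o = min(n10, n01)
    return s + o, s, s


def _merge(best: dict, key, pairs: int, b: int, w: int) -> None:
    cur = best.get(key)
    if cur is None or pairs > cur[0]:
        best[key] = (pairs, b, w)
    elif pairs == cur[0]:
        best[key] = (pairs, max(cur[1], b), min(cur[2], w))


def _combine_children(child_states: list[dict]) -> dict:
    """Fold children into node states over dangle-count vectors."""
    acc: dict[tuple[int, int, int, int], tuple[int, int, int]] = {
        (0, 0, 0, 0): (0, 0, 0)
    }
    for states in child_states:
        nxt: dict = {}
        for vec, (pairs, b, w) in acc.items():
            for state, (cp, cb, cw) in states.items():
                if state == "none":
                    nvec = vec
                else:
                    i = _DANGLES.index(state)
                    nvec = tuple(v + (1 if j == i else 0) for j, v in enumerate(vec))
                _merge(nxt, nvec, pairs + cp, b + cb, w + cw)
        acc = nxt
    out: dict = {}
    for vec, (pairs, b, w) in acc.items():
        m, smax, smin = _match_stats(*vec)
        _merge(out, "none", pairs + m, b + smax, w + smin)
        for i, dangle in enumerate(_DANGLES):
            if vec[i] == 0:
                continue
            rvec = tuple(v - (1 if j == i else 0) for j, v in enumerate(vec))
            m, smax, smin = _match_stats(*rvec)
            _merge(out, dangle, pairs + m, b + smax, w + smin)
    return out


def max_contrasting_pairs(
    tree: dendropy.Tree,
    genotype: Mapping[str, int],
    phenotype: Mapping[str, int],
) -> PairSummary:
    """Maximum phylogenetically independent contrasting pairs on a tree.

    Tips missing either trait (or with a missing value) are pruned first;
    trait-table entries absent from the tree are pruned with a warning.
    Polytomies are handled exactly (several pairs may cross one polytomy
    as long as no edge is reused).
    """

    def _clean(d: Mapping[str, int]) -> dict[str, int]:
        return {
            k: int(v)
            for k, v in d.items()
            if v is not None and not (isinstance(v, float) and math.isnan(v))
        }

    geno, pheno = _clean(genotype), _clean(phenotype)
    tip_labels = {
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    }
    extra = (set(geno) | set(pheno)) - tip_labels
    if extra:
        warnings.warn(
            f"{len(extra)} trait-table genome(s) absent from tree, pruned"
        )
    usable = {t for t in tip_labels if t in geno and t in pheno}

    def solve(node) -> dict:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in usable:
                return {"none": (0, 0, 0)}
            state = (geno[label], pheno[label])
            return {"none": (0, 0, 0), state: (0, 0, 0)}
        return _combine_children([solve(c) for c in node.child_nodes()])

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10_000))
    try:
        root_states = solve(tree.seed_node)
    finally:
        sys.setrecursionlimit(old_limit)
    max_pairs, best, worst = root_states["none"]
    if max_pairs == 0:
        return PairSummary(0, 0, 0, float("nan"), float("nan"))
    p_best = float(sps.binom.sf(best - 1, max_pairs, 0.5))
    p_worst = float(sps.binom.sf(worst - 1, max_pairs, 0.5))
    return PairSummary(max_pairs, best, worst, p_best, p_worst)


def trait_association(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    presence_column: str,
) -> pd.DataFrame:
    """Fisher + contrasting-pairs association of every trait with presence.

    ``traits`` has genomes as rows; ``presence_column`` names the binary
    genotype column (e.g. eCIS presence).  Each other column is tested:
    one Fisher 2x2 over genomes with both values, plus the pairwise test
    on the tree.  Missing values prune genomes per trait, not globally.
    """
    genotype = traits[presence_column]
    rows = []
    for col in traits.columns:
        if col == presence_column:
            continue
        pair = traits[[presence_column, col]].dropna()
        a = int(((pair[presence_column] == 1) & (pair[col] == 1)).sum())
        b = int(((pair[presence_column] == 1) & (pair[col] == 0)).sum())
        c = int(((pair[presence_column] == 0) & (pair[col] == 1)).sum())
        d = int(((pair[presence_column] == 0) & (pair[col] == 0)).sum())
        oratio, p = fisher_exact_2x2(a, b, c, d)
        ps = max_contrasting_pairs(
            tree, pair[presence_column].to_dict(), pair[col].to_dict()
        )
        rows.append(
            {"trait": col, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": oratio, "fisher_p": p, "max_pairs": ps.max_pairs,
             "best_support": ps.best_support, "worst_support": ps.worst_support,
             "p_best": ps.p_best, "p_worst": ps.p_worst}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fisher_q"] = bh_adjust(df["fisher_p"].to_numpy())
    return df
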