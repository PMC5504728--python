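"""Independent brute-force reference for the best-pair search.

Deliberately written from scratch against the definitions alone — plain
nested loops over alleles and markers, no numpy, no reuse of the package's
scoring path — so it can serve as an oracle for the vectorized search.
"""

import itertools
import math


def naive_pair_D(ind, allele1, allele2, table):
    """(D, n_used) by direct per-marker evaluation."""
    D = 0.0
    n_used = 0
    for m in table.markers:
        post = ind.posteriors.get(m.id)
        if post is None:
            continue
        b1 = allele1.bases.get(m.id, "?")
        b2 = allele2.bases.get(m.id, "?")
        if b1 == "?" or b2 == "?":
            continue
        n_used += 1
        if b1 not in (m.alleleA, m.alleleB) or b2 not in (m.alleleA, m.alleleB):
            D += 1.0
            continue
        n_b = int(b1 == m.alleleB) + int(b2 == m.alleleB)
        p = (post.p_AA, post.p_AB, post.p_BB)[n_b]
        D += min(1.0, max(0.0, 1.0 - p))
    return D, n_used


def naive_best_pairs(ind, table, min_coverage=0.5, tie_tol=1e-9):
    """(D_min, argmin pair set) by exhaustive double loop."""
    alleles = [
        a for a in table.alleles
        if sum(a.bases.get(m.id, "?") != "?" for m in table.markers)
        >= min_coverage * len(table.markers)
    ]
    best = math.inf
    scores = []
    for a1, a2 in itertools.combinations_with_replacement(alleles, 2):
        D, n_used = naive_pair_D(ind, a1, a2, table)
        if n_used == 0:
            continue
        names = tuple(sorted((a1.name, a2.name)))
        scores.append((names, D))
        best = min(best, D)
    return best, {names for names, D in scores if D <= best + tie_tol}
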