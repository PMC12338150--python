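"""Independent oracles used by the test suite.

These deliberately do not share code with the package: masses are summed
from an independently keyed-in atomic mass table, cutoff selection is an
exhaustive scan, and operon windows are found by brute-force subset search.
"""

from itertools import combinations

# NIST/CODATA monoisotopic atomic masses, keyed in independently of the
# package's mass backend.
ATOMIC_MONO = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

PROTON = 1.00727646688
WATER = 2 * ATOMIC_MONO["H"] + ATOMIC_MONO["O"]


def formula_mass(counts: dict) -> float:
    """Brute-force elemental summation."""
    return sum(n * ATOMIC_MONO[e] for e, n in counts.items())


def exhaustive_cutoff(pos, neg):
    """Scan every observed score as a threshold; minimal t at maximal F."""
    pos, neg = list(pos), list(neg)
    best_t, best_f = None, -1.0
    for t in sorted(set(pos) | set(neg)):
        tp = sum(1 for p in pos if p >= t)
        fp = sum(1 for n in neg if n >= t)
        fn = len(pos) - tp
        if tp == 0:
            f = 0.0
        else:
            recall = tp / (tp + fn)
            precision = tp / (tp + fp)
            f = 2.0 / (1.0 / recall + 1.0 / precision)
        if f > best_f:
            best_t, best_f = t, f
    return best_t, best_f


def brute_force_operon(hits, coords, window):
    """Best co-localized distinct-gene subset by exhaustive enumeration.

    ``hits``: [(gene, cds_id)]; ``coords``: cds_id -> (contig, start, end).
    Returns (max distinct genes, min span among maxima) over subsets with
    distinct genes on one contig whose span (max end - min start) is below
    ``window``.
    """
    placed = [(g, *coords[c]) for g, c in hits if c in coords]
    best_n, best_span = 0, 0
    for r in range(1, len(placed) + 1):
        for sub in combinations(placed, r):
            if len({s[1] for s in sub}) != 1:        # one contig
                continue
            genes = {s[0] for s in sub}
            if len(genes) != len(sub):               # distinct genes only
                continue
            span = max(s[3] for s in sub) - min(s[2] for s in sub)
            if span >= window:
                continue
            if (len(genes), -span) > (best_n, -best_span):
                best_n, best_span = len(genes), span
    return best_n, best_span
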