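"""Independent brute-force oracles used to validate the statistics.

Everything here is deliberately written from first principles (direct
enumeration, exact rational arithmetic where possible) and shares no
code with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

DNA = "ACGT"

GENETIC_CODE = {}


def _fill_code():
    # built from Bio's table once, then used as a plain dict
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    t = unambiguous_dna_by_id[1]
    for c in itertools.product(DNA, repeat=3):
        codon = "".join(c)
        GENETIC_CODE[codon] = "*" if codon in t.stop_codons else t.forward_table[codon]


_fill_code()


def hunter_gaston_exact(counts) -> Fraction:
    counts = list(counts)
    n = sum(counts)
    return 1 - Fraction(sum(c * (c - 1) for c in counts), n * (n - 1))


def clean_columns(seqs):
    return [c for c in zip(*seqs) if all(b in DNA for b in c)]


def polymorphic_sites_scan(seqs) -> int:
    return sum(len(set(c)) > 1 for c in clean_columns(seqs))


def pairwise_pi(seqs) -> float:
    cols = clean_columns(seqs)
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    total = sum(sum(c[i] != c[j] for c in cols) for i, j in pairs)
    return total / len(pairs) / len(cols)


def tajima_d_direct(seqs):
    """Direct evaluation of Tajima's statistic from its defining constants."""
    n = len(seqs)
    cols = clean_columns(seqs)
    s = sum(len(set(c)) > 1 for c in cols)
    if s == 0:
        return None
    pairs = list(itertools.combinations(range(n), 2))
    khat = sum(sum(c[i] != c[j] for c in cols) for i, j in pairs) / len(pairs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (khat - s / float(a1)) / math.sqrt(float(e1) * s + float(e2) * s * (s - 1))


def codon_path_counts(c1: str, c2: str):
    """(syn, nonsyn) step counts averaged over all orderings of the
    differing positions, by recursive enumeration of complete paths."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []

    def walk(cur, remaining, syn, non):
        if not remaining:
            paths.append((syn, non))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            step_syn = GENETIC_CODE[nxt] == GENETIC_CODE[cur]
            walk(nxt, [p for p in remaining if p != pos],
                 syn + step_syn, non + (not step_syn))

    walk(c1, diff, 0, 0)
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def ng86_pair(seq1, seq2):
    """Full NG86 + Jukes-Cantor oracle on codon-aligned sequences."""
    codons = [(seq1[i:i + 3], seq2[i:i + 3]) for i in range(0, len(seq1), 3)]
    s_sites = 0.0
    for c1, c2 in codons:
        for c in (c1, c2):
            aa = GENETIC_CODE[c]
            syn = sum(
                GENETIC_CODE[c[:p] + b + c[p + 1:]] == aa
                for p in range(3) for b in DNA if b != c[p]
            )
            s_sites += syn / 3.0 / 2.0
    n_sites = 3.0 * len(codons) - s_sites
    sd = nd = 0.0
    for c1, c2 in codons:
        s, n = codon_path_counts(c1, c2)
        sd += s
        nd += n
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)  # noqa: E731
    return jc(pn), jc(ps)


def ia_enumerate(profiles):
    """I_A by literal enumeration of all unit pairs."""
    n = len(profiles)
    loci = len(profiles[0])
    ks = [
        sum(a != b for a, b in zip(profiles[i], profiles[j]))
        for i, j in itertools.combinations(range(n), 2)
    ]
    mean = sum(ks) / len(ks)
    v_o = sum((k - mean) ** 2 for k in ks) / len(ks)
    v_e = 0.0
    for l in range(loci):
        col = [p[l] for p in profiles]
        h = 1 - sum((col.count(a) / n) ** 2 for a in set(col))
        v_e += h * (1 - h)
    return v_o / v_e - 1


def spanning_tree_min_weight(n_nodes, dist):
    """Exact MST weight by brute force over all spanning edge subsets."""
    edges = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    best = None
    for subset in itertools.combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            w = sum(dist[a][b] for a, b in subset)
            if best is None or w < best:
                best = w
    return best


def ari_contingency(labels_a, labels_b):
    """Adjusted Rand index from the contingency table, by hand."""
    from collections import Counter

    n = len(labels_a)
    table = Counter(zip(labels_a, labels_b))
    a = Counter(labels_a)
    b = Counter(labels_b)
    comb2 = lambda x: x * (x - 1) // 2  # noqa: E731
    sum_ij = sum(comb2(v) for v in table.values())
    sum_a = sum(comb2(v) for v in a.values())
    sum_b = sum(comb2(v) for v in b.values())
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
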