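"""Discriminatory power, sequence diversity and multilocus linkage.

Implements the classical typing and population-genetic statistics:

* Hunter-Gaston discriminatory index — Simpson's diversity with the
  finite-sample correction, D = 1 - sum n_j(n_j-1) / (N(N-1)), the
  probability that two randomly drawn isolates have different types,
  with a large-sample 95% confidence interval.
* Per-locus alignment statistics: segregating sites S, G+C content,
  nucleotide diversity pi (mean pairwise difference per site), Tajima's
  D (normalised difference between pi-based and Watterson estimates of
  theta), and Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.
* The index of association I_A (and its loci-scaled variant sI_A) —
  the excess of observed variance in pairwise multilocus mismatch
  counts over the variance expected under linkage equilibrium, with a
  within-locus permutation test.

Alignment statistics use complete deletion: columns containing anything
other than A/C/G/T are dropped before counting.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from Bio.Data import CodonTable

from .scheme import DNA_ALPHABET, IsolateRecord, SchemeDef, default_scheme

__all__ = [
    "HunterGastonResult",
    "simpson_hunter_gaston",
    "allele_count_per_locus",
    "LocusAlignment",
    "polymorphic_sites",
    "gc_content",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "tajimas_d",
    "SaturationError",
    "nei_gojobori_pair",
    "dnds_alignment",
    "IAResult",
    "index_of_association",
]


# ---------------------------------------------------------------------------
# Discriminatory power


@dataclass(frozen=True)
class HunterGastonResult:
    d: float
    ci_low: float
    ci_high: float
    n: int


def simpson_hunter_gaston(counts: Iterable[int], z: float = 1.96) -> HunterGastonResult:
    """Hunter-Gaston discriminatory index with a large-sample 95% CI.

    The CI uses the standard large-sample variance of Simpson's index,
    sigma^2 = (4/N) * [sum p_j^3 - (sum p_j^2)^2], clipped to [0, 1].
    """
    counts = np.asarray(list(counts), dtype=float)
    if np.any(counts < 1):
        raise ValueError("type counts must all be >= 1")
    n = counts.sum()
    if n < 2:
        raise ValueError("Hunter-Gaston D needs at least 2 isolates")
    d = 1.0 - float((counts * (counts - 1)).sum()) / (n * (n - 1))
    p = counts / n
    var = (4.0 / n) * float((p**3).sum() - (p**2).sum() ** 2)
    half = z * math.sqrt(max(var, 0.0))
    return HunterGastonResult(d, max(d - half, 0.0), min(d + half, 1.0), int(n))


def allele_count_per_locus(records: Iterable[IsolateRecord],
                           scheme: Optional[SchemeDef] = None) -> dict[str, int]:
    """Distinct allele numbers observed per locus column of a profile table."""
    scheme = scheme or default_scheme()
    seen: dict[str, set[int]] = {name: set() for name in scheme.locus_names}
    any_profile = False
    for rec in records:
        if rec.profile is None:
            continue
        any_profile = True
        for name, allele in zip(scheme.locus_names, rec.profile):
            seen[name].add(allele)
    if not any_profile:
        raise ValueError("no resolved profiles in input")
    return {name: len(alleles) for name, alleles in seen.items()}


# ---------------------------------------------------------------------------
# Alignment statistics


@dataclass(frozen=True)
class LocusAlignment:
    """Equal-length DNA sequences for one locus (per isolate or per allele)."""

    locus: str
    seqs: tuple[str, ...]
    frame: int = 0  # reading-frame offset for coding statistics

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("alignment must contain at least one sequence")
        seqs = tuple(s.upper() for s in self.seqs)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        object.__setattr__(self, "seqs", seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.seqs)

    def clean_columns(self) -> list[int]:
        """Indices of columns containing only A/C/G/T (complete deletion)."""
        return [
            j for j in range(self.length)
            if all(s[j] in DNA_ALPHABET for s in self.seqs)
        ]


def polymorphic_sites(a: LocusAlignment) -> int:
    """Segregating sites S: clean columns carrying >= 2 distinct bases."""
    return sum(len({s[j] for s in a.seqs}) > 1 for j in a.clean_columns())


def gc_content(a: LocusAlignment) -> float:
    """G+C fraction pooled over all sequences (A/C/G/T bases only)."""
    gc = acgt = 0
    for s in a.seqs:
        for base in s:
            if base in DNA_ALPHABET:
                acgt += 1
                if base in "GC":
                    gc += 1
    if acgt == 0:
        raise ValueError("no countable A/C/G/T bases")
    return gc / acgt


def _pairwise_diffs(a: LocusAlignment, cols: Sequence[int]) -> list[int]:
    return [
        sum(s1[j] != s2[j] for j in cols)
        for s1, s2 in itertools.combinations(a.seqs, 2)
    ]


def mean_pairwise_differences(a: LocusAlignment) -> float:
    """Mean pairwise difference count k-hat over clean columns."""
    if a.n < 2:
        raise ValueError("need >= 2 sequences")
    diffs = _pairwise_diffs(a, a.clean_columns())
    return sum(diffs) / len(diffs)


def nucleotide_diversity(a: LocusAlignment) -> float:
    """Nei's per-site pi: mean pairwise differences / retained length."""
    if a.n < 2:
        raise ValueError("need >= 2 sequences")
    cols = a.clean_columns()
    if not cols:
        raise ValueError("no clean columns to compare")
    return mean_pairwise_differences(a) / len(cols)


def tajimas_d(a: LocusAlignment) -> Optional[float]:
    """Tajima's D from k-hat and S.

    Returns None when S = 0 (the statistic is undefined for a
    monomorphic alignment); raises for n < 4.
    """
    n = a.n
    if n < 4:
        raise ValueError(f"Tajima's D needs n >= 4 sequences, got {n}")
    s = polymorphic_sites(a)
    if s == 0:
        return None
    khat = mean_pairwise_differences(a)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) dN/dS

_BASES = "ACGT"
_CODON_AA: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_AA:
        table = CodonTable.unambiguous_dna_by_id[1]
        for c in itertools.product(_BASES, repeat=3):
            codon_s = "".join(c)
            _CODON_AA[codon_s] = (
                "*" if codon_s in table.stop_codons else table.forward_table[codon_s]
            )
    return _CODON_AA[codon]


class SaturationError(ValueError):
    """Proportion of differences >= 3/4: Jukes-Cantor correction undefined."""


def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon: per position, the fraction of the
    three possible single-base changes that preserve the amino acid."""
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                mutant = codon[:pos] + base + codon[pos + 1:]
                if _aa(mutant) == aa0:
                    s += 1.0 / 3.0
    return s


def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts for one codon pair,
    averaged over all equally weighted mutational pathways."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    paths = list(itertools.permutations(positions))
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == _aa(cur):
                sd_total += 1
            else:
                nd_total += 1
            cur = nxt
    return sd_total / len(paths), nd_total / len(paths)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4, distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_pair(seq1: str, seq2: str) -> tuple[float, float]:
    """(dN, dS) for a codon-aligned sequence pair, NG86 counting with
    Jukes-Cantor correction.

    Pathways through premature stop codons are retained with equal
    weight (a step is synonymous iff the encoded residue, stop included,
    is unchanged); internal stop codons in the inputs are rejected.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError(f"length {len(seq1)} is not a multiple of 3")
    codons1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]
    for c in itertools.chain(codons1[:-1], codons2[:-1]):
        if _aa(c) == "*":
            raise ValueError(f"internal stop codon {c}")
    s_sites = sum((_syn_sites(c1) + _syn_sites(c2)) / 2.0 for c1, c2 in zip(codons1, codons2))
    n_sites = 3.0 * len(codons1) - s_sites
    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        d_s, d_n = _codon_pair_diffs(c1, c2)
        sd += d_s
        nd += d_n
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    return _jukes_cantor(p_n), _jukes_cantor(p_s)


def dnds_alignment(a: LocusAlignment) -> tuple[float, float, Optional[float]]:
    """Mean dN and dS over all unordered pairs; ratio = mean dN / mean dS.

    Saturated pairs are excluded with a warning; the ratio is None when
    mean dS = 0 (no synonymous divergence to normalise by).
    """
    if a.n < 2:
        raise ValueError("need >= 2 sequences")
    start = a.frame
    usable = (a.length - start) // 3 * 3
    dns, dss = [], []
    for s1, s2 in itertools.combinations(a.seqs, 2):
        try:
            dn, ds = nei_gojobori_pair(s1[start:start + usable], s2[start:start + usable])
        except SaturationError as exc:
            warnings.warn(f"{a.locus}: pair excluded ({exc})", stacklevel=2)
            continue
        dns.append(dn)
        dss.append(ds)
    if not dns:
        raise ValueError("all pairs saturated")
    mean_dn = sum(dns) / len(dns)
    mean_ds = sum(dss) / len(dss)
    ratio = mean_dn / mean_ds if mean_ds > 0 else None
    return mean_dn, mean_ds, ratio


# ---------------------------------------------------------------------------
# Index of association


@dataclass(frozen=True)
class IAResult:
    ia: float
    s_ia: float
    p_value: Optional[float]
    n_perm: int
    v_o: float
    v_e: float
    seed: Optional[int] = None


def _mismatch_vectors(arr: np.ndarray) -> np.ndarray:
    """Per-locus condensed pair-mismatch indicators, shape (L, n_pairs)."""
    n = arr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return (arr[iu, :] != arr[ju, :]).T.astype(float)


def _ia_from_k(k: np.ndarray, v_e: float, n_loci: int) -> float:
    return float(k.var()) / v_e - 1.0


def index_of_association(profiles: Sequence[Sequence[int]], unit: str = "isolates",
                         n_perm: int = 0, seed: Optional[int] = None) -> IAResult:
    """Multilocus index of association I_A with a permutation test.

    K_ij is the profile mismatch count between units i and j; V_O is the
    population variance of K over all unordered pairs; V_E = sum_l
    h_l (1 - h_l) with h_l = 1 - sum_a p_la^2 the per-locus mismatch
    probability.  I_A = V_O / V_E - 1 and sI_A = I_A / (L - 1).  Clonal
    (linked) data give I_A > 0; free recombination gives I_A ~ 0.

    The p-value is the fraction of ``n_perm`` datasets — alleles
    permuted independently within each locus — with I_A >= observed.
    ``unit='unique'`` collapses identical profiles to single units
    first (the LIAN "haplotype" convention).
    """
    arr = np.asarray([tuple(p) for p in profiles], dtype=int)
    if arr.ndim != 2:
        raise ValueError("profiles must be a rectangular table")
    if unit == "unique":
        arr = np.unique(arr, axis=0)
    elif unit != "isolates":
        raise ValueError(f"unit must be 'isolates' or 'unique', got {unit!r}")
    n, n_loci = arr.shape
    if n < 2:
        raise ValueError("need >= 2 units")
    if n_loci < 2:
        raise ValueError("need >= 2 loci (sI_A divides by L - 1)")

    v_e = 0.0
    for l in range(n_loci):
        _, counts = np.unique(arr[:, l], return_counts=True)
        h = 1.0 - float(((counts / n) ** 2).sum())
        v_e += h * (1.0 - h)
    if v_e == 0.0:
        raise ValueError("monomorphic data: expected variance is zero")

    mism = _mismatch_vectors(arr)  # (L, n_pairs)
    k_obs = mism.sum(axis=0)
    ia = _ia_from_k(k_obs, v_e, n_loci)
    s_ia = ia / (n_loci - 1)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n, k=1)
        k_perm = np.zeros((n_perm, iu.size))
        for l in range(n_loci):
            cols = rng.permuted(np.tile(arr[:, l], (n_perm, 1)), axis=1)
            k_perm += cols[:, iu] != cols[:, ju]
        ia_perm = k_perm.var(axis=1) / v_e - 1.0
        p_value = float(np.mean(ia_perm >= ia))
    return IAResult(ia=ia, s_ia=s_ia, p_value=p_value, n_perm=n_perm,
                    v_o=float(k_obs.var()), v_e=v_e, seed=seed)
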