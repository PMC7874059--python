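"""Synthetic clonal populations with known structure, linkage and phenotypes.

The generator emulates the shape of the study collection: a handful of
founder genotypes, each expanded into descendants that occasionally
acquire a single-locus variant (a novel allele one substitution away
from the founder's, so every SLV at the profile level is Hamming-1 at
the sequence level) or, with a separate tunable rate, a recombinant
allele drawn from the existing pool.  Every strain's true founder,
profile and ST are recorded, so allele calling, eBURST grouping and
linkage statistics can be validated against ground truth.

The ``qinghai`` preset mirrors the study: 45 strains over 8 loci with
the scheme's fragment lengths — 41 field isolates in multi-strain
founder groups (sources potato 16, oat 7, wheat 2, Qula 16) plus 4
reference strains as singleton founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import PhenotypeMatrix, TERNARY_SCORES
from .scheme import AlleleDatabase, STRegistry

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimPopulation",
    "gen_allele_pool",
    "gen_population",
    "gen_phenotypes",
    "qinghai_config",
    "write_population",
]

_BASES = np.array(list("ACGT"))

#: Canonical-order fragment lengths of the packaged scheme.
DEFAULT_LOCI = ("pyrG", "rpoB", "groEL", "recA", "uvrC", "carB", "murC", "pheS")
DEFAULT_LENGTHS = (598, 608, 656, 550, 560, 833, 619, 665)


@dataclass(frozen=True)
class SimConfig:
    loci: tuple[str, ...] = DEFAULT_LOCI
    fragment_lengths: tuple[int, ...] = DEFAULT_LENGTHS
    founder_sizes: tuple[int, ...] = (5, 5, 5)  # strains per founder, founder included
    pool_alleles: int = 6  # ancestral alleles per locus
    min_pool_diff: int = 3  # min pairwise Hamming within a pool
    min_founder_dist: int = 4  # min profile distance between founders
    slv_rate: float = 0.3  # P(descendant gains one novel-allele SLV)
    recombination_rate: float = 0.0  # P(descendant swaps one locus to a pool allele)
    n_wells: int = 49
    concordance: float = 0.9  # kappa: P(well copied from the founder prototype)
    seed: Optional[int] = None
    sources: tuple[str, ...] = ()  # optional per-strain source labels

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.fragment_lengths):
            raise ValueError("loci and fragment_lengths must align")
        for p in (self.slv_rate, self.recombination_rate, self.concordance):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")
        if any(l <= 0 for l in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")
        if self.sources and len(self.sources) != sum(self.founder_sizes):
            raise ValueError("sources must have one label per strain")


def qinghai_config(seed: Optional[int] = None, **overrides) -> SimConfig:
    """Study-shaped preset: 41 field isolates in 9 founder groups plus 4
    reference singletons; 45 strains total."""
    sizes = (8, 6, 6, 5, 4, 4, 3, 3, 2) + (1, 1, 1, 1)
    sources = (
        ("potato",) * 16 + ("Qula",) * 16 + ("oat",) * 7 + ("wheat",) * 2
        + ("standard",) * 4
    )
    return SimConfig(founder_sizes=sizes, sources=sources, seed=seed, **overrides)


def gen_allele_pool(length: int, n_alleles: int, min_pairwise_diff: int = 1,
                    rng: Optional[np.random.Generator] = None,
                    seed: Optional[int] = None) -> list[str]:
    """Equal-length random sequences, all pairwise Hamming >= min_pairwise_diff."""
    if n_alleles < 1 or min_pairwise_diff < 1:
        raise ValueError("need n_alleles >= 1 and min_pairwise_diff >= 1")
    if min_pairwise_diff > length:
        raise ValueError("min_pairwise_diff exceeds sequence length")
    rng = rng if rng is not None else np.random.default_rng(seed)
    base = "".join(rng.choice(_BASES, size=length))
    pool = [base]
    attempts = 0
    while len(pool) < n_alleles:
        attempts += 1
        if attempts > 1000 * n_alleles:
            raise ValueError(
                f"could not place {n_alleles} alleles of length {length} "
                f"at pairwise distance >= {min_pairwise_diff}"
            )
        # mutate the base at min_diff + slack random positions
        k = min(min_pairwise_diff + len(pool), length)
        cand = list(base)
        for pos in rng.choice(length, size=k, replace=False):
            cand[pos] = rng.choice([b for b in "ACGT" if b != cand[pos]])
        cand = "".join(cand)
        if all(sum(a != b for a, b in zip(cand, p)) >= min_pairwise_diff for p in pool):
            pool.append(cand)
    return pool


@dataclass
class GroundTruth:
    founder_of: dict[str, str]  # strain -> founder strain id
    profile_of: dict[str, tuple[int, ...]]
    st_of: dict[str, int]
    founder_st: dict[str, int]  # founder strain id -> its ST
    registry: STRegistry = field(repr=False)
    db: AlleleDatabase = field(repr=False)  # includes all novel mutant alleles

    def components(self) -> dict[str, set[int]]:
        """True founder-descendant ST components (founder id -> ST set)."""
        comps: dict[str, set[int]] = {}
        for strain, founder in self.founder_of.items():
            comps.setdefault(founder, set()).add(self.st_of[strain])
        return comps


@dataclass
class SimPopulation:
    config: SimConfig
    sequences: dict[str, dict[str, str]]  # strain -> locus -> fragment
    metadata: pd.DataFrame
    truth: GroundTruth


def gen_population(cfg: SimConfig) -> SimPopulation:
    """Simulate founders and clonally expanded descendants.

    Founder profiles are drawn over the ancestral pools at pairwise
    profile distance >= ``min_founder_dist`` so that descendant groups
    remain separable in the SLV graph.  Mutation events per descendant:
    one novel-allele SLV with probability ``slv_rate`` and,
    independently, one pool-allele swap with ``recombination_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    db = AlleleDatabase()
    for locus, length in zip(cfg.loci, cfg.fragment_lengths):
        for seq in gen_allele_pool(length, cfg.pool_alleles, cfg.min_pool_diff, rng=rng):
            db.register(locus, seq)

    n_loci = len(cfg.loci)
    founder_profiles: list[tuple[int, ...]] = []
    guard = 0
    while len(founder_profiles) < len(cfg.founder_sizes):
        guard += 1
        if guard > 100000:
            raise ValueError("cannot place founder profiles at the requested distance")
        cand = tuple(int(rng.integers(1, cfg.pool_alleles + 1)) for _ in range(n_loci))
        if all(sum(a != b for a, b in zip(cand, p)) >= cfg.min_founder_dist
               for p in founder_profiles):
            founder_profiles.append(cand)

    registry = STRegistry(n_loci=n_loci)
    sequences: dict[str, dict[str, str]] = {}
    founder_of: dict[str, str] = {}
    profile_of: dict[str, tuple[int, ...]] = {}
    st_of: dict[str, int] = {}
    founder_st: dict[str, int] = {}
    rows = []
    strain_no = 0
    for g, (size, fprofile) in enumerate(zip(cfg.founder_sizes, founder_profiles), start=1):
        founder_id = f"f{g:02d}"
        for k in range(size):
            strain = founder_id if k == 0 else f"f{g:02d}d{k:02d}"
            profile = list(fprofile)
            if k > 0:
                if rng.random() < cfg.slv_rate:
                    locus_i = int(rng.integers(n_loci))
                    locus = cfg.loci[locus_i]
                    parent_seq = db.sequence(locus, profile[locus_i])
                    while True:  # one substitution, guaranteed novel
                        pos = int(rng.integers(len(parent_seq)))
                        base = rng.choice([b for b in "ACGT" if b != parent_seq[pos]])
                        mutant = parent_seq[:pos] + base + parent_seq[pos + 1:]
                        if db.lookup(locus, mutant) is None:
                            break
                    profile[locus_i] = db.register(locus, mutant)
                if rng.random() < cfg.recombination_rate:
                    locus_i = int(rng.integers(n_loci))
                    locus = cfg.loci[locus_i]
                    choices = [a for a in range(1, db.n_alleles(locus) + 1)
                               if a != profile[locus_i]]
                    if choices:
                        profile[locus_i] = int(rng.choice(choices))
            profile = tuple(profile)
            st = registry.assign(profile)
            sequences[strain] = {
                locus: db.sequence(locus, allele)
                for locus, allele in zip(cfg.loci, profile)
            }
            founder_of[strain] = founder_id
            profile_of[strain] = profile
            st_of[strain] = st
            if k == 0:
                founder_st[founder_id] = st
            source = cfg.sources[strain_no] if cfg.sources else f"group{g}"
            rows.append({"isolate": strain, "founder": founder_id, "ST": st,
                         "source": source})
            strain_no += 1

    truth = GroundTruth(founder_of=founder_of, profile_of=profile_of, st_of=st_of,
                        founder_st=founder_st, registry=registry, db=db)
    return SimPopulation(config=cfg, sequences=sequences,
                         metadata=pd.DataFrame(rows), truth=truth)


def gen_phenotypes(truth: GroundTruth, concordance: float, n_wells: int = 49,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> PhenotypeMatrix:
    """Ternary well profiles correlated with genotype clusters.

    Each founder group gets a random prototype pattern; each strain
    copies each prototype well with probability ``concordance`` and
    otherwise draws uniformly from {0, 0.5, 1}.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    scores = np.array(TERNARY_SCORES)
    prototypes = {
        founder: rng.choice(scores, size=n_wells)
        for founder in sorted(set(truth.founder_of.values()))
    }
    rows = {}
    for strain in truth.founder_of:
        proto = prototypes[truth.founder_of[strain]]
        copy = rng.random(n_wells) < concordance
        noise = rng.choice(scores, size=n_wells)
        rows[strain] = np.where(copy, proto, noise)
    data = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"well{i + 1}" for i in range(n_wells)])
    return PhenotypeMatrix(data=data)


def write_population(pop: SimPopulation, directory: str | Path) -> None:
    """Write per-isolate locus FASTA (headers ``<isolate>|<locus>``), a
    truth/metadata TSV and the generating allele database."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for strain, loci in pop.sequences.items():
        for locus, seq in loci.items():
            lines.append(f">{strain}|{locus}")
            lines.extend(seq[i:i + 80] for i in range(0, len(seq), 80))
    (directory / "isolates.fasta").write_text("\n".join(lines) + "\n")
    pop.metadata.to_csv(directory / "truth.tsv", sep="\t", index=False)
    pop.truth.db.to_fasta_dir(directory / "alleles")
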