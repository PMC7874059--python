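# mlstpop

Population-structure analysis for bacterial multilocus sequence typing
(MLST), built around an eight-locus housekeeping-gene scheme for
*Leuconostoc mesenteroides* (`pyrG, rpoB, groEL, recA, uvrC, carB, murC,
pheS`).  The package is aimed at microbiologists typing isolate
collections from food and environmental sources who want the full
downstream analysis — clonal structure, diversity, linkage, and
genotype–phenotype comparison — reproducible from a plain profile table.

## What it computes

- **Allele / ST assignment.**  Each locus fragment is matched exactly
  against a numbered allele database; the ordered 8-tuple of allele
  numbers (the *allelic profile*) maps bijectively to a sequence type
  (ST).  Novel alleles and STs are numbered max+1 in first-seen order.
- **eBURST clonal complexes.**  STs sharing 7/8 loci are single-locus
  variants (SLVs); connected components of the SLV graph with ≥ 3
  members are clonal complexes (CCs), named after the predicted founder
  — the member with the most SLVs (ties: DLV count, isolate count,
  lower ST).
- **Minimum spanning tree** over all STs (Prim's algorithm on profile
  mismatch counts, deterministic tie-breaks).
- **Discriminatory power:** the Hunter–Gaston index
  `D = 1 − Σ n_j(n_j−1) / (N(N−1))` with a large-sample 95% CI.
- **Per-locus sequence diversity:** segregating sites *S*, G+C content,
  nucleotide diversity π, Tajima's *D*, and Nei–Gojobori (1986) dN/dS
  with Jukes–Cantor correction.
- **Multilocus linkage:** the index of association
  `I_A = V_O/V_E − 1` (and `sI_A = I_A/(L−1)`) with a within-locus
  permutation test — positive under clonality, ≈ 0 under free
  recombination.
- **Clustering:** categorical UPGMA dendrograms of STs, Manhattan
  clustering of ternary 49-well carbon-source (API 50CH-style)
  phenotypes, and Adjusted-Rand concordance between the two.
- **Synthetic populations** with known founders, SLV/recombination
  rates and phenotype concordance, for end-to-end validation.

The 42-row published profile matrix of the Qinghai–Tibet Plateau
*L. mesenteroides* collection ships as a packaged fixture, together
with isolate metadata and the scheme definition.

## Worked example

```python
from mlstpop import (fixture_records, ProfileMatrix, burst_groups,
                     simpson_hunter_gaston, index_of_association)
from collections import Counter

records = fixture_records()                      # 42 isolates, 24 STs
pm = ProfileMatrix.from_records(records)
part = burst_groups(pm)
cc = part.clonal_complexes[0]
print(cc.name, cc.members, [g.members for g in part.doublets])
# CC9 (5, 9, 12, 17) [(6, 13), (8, 25), (18, 19)]

counts = Counter(r.st for r in records)
print(round(simpson_hunter_gaston(counts.values()).d, 4))
# 0.9652

ia = index_of_association([r.profile for r in records], n_perm=500, seed=0)
print(round(ia.ia, 4), ia.p_value)
# 1.1933 0.0
```

One clonal complex (CC9 = {ST5, ST9, ST12, ST17}, 10 isolates) emerges
from the printed profiles, alongside three doublets; the collection is
highly diverse (D ≈ 0.97) yet strongly linked (I_A ≫ 0, permutation
p < 0.002), the classic signature of an epidemic/clonal population.

The same analyses are available from the shell:

```bash
mlstpop report --out results/        # profiles → eBURST → MST → diversity → UPGMA
mlstpop simulate --seed 42 --out sim/  # synthetic population with ground truth
mlstpop call --alleles sim/alleles --fasta sim/isolates.fasta --out called.tsv
```

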