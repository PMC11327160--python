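# A Lamiales-like demo history: an 11-proto-chromosome ancestor splits into
# a reference lineage that keeps the ancestral karyotype and a query lineage
# that undergoes one whole-genome duplication (the shared-WGD analog),
# biased fractionation, and the 2 EEJ + 4 NCF fusion inventory that reduces
# 22 chromosomes to n = 16.
ancestor:
  n_chromosomes: 11
  genes_per_chromosome: 200
split_age: 1.5
lineages:
  REF: []
  LPHI:
    - {kind: WGD, age: 0.75}
    - {kind: LOSS, retention: {A: 0.8, B: 0.6}}
    - {kind: EEJ}
    - {kind: EEJ}
    - {kind: NCF}
    - {kind: NCF}
    - {kind: NCF}
    - {kind: NCF}
homologs:
  - [LPHI, LPHI]
  - [LPHI, REF]
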