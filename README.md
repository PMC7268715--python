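# cas16s

Design host-specific Cas9 guide RNAs for depleting organelle 16S rRNA gene
contamination in amplicon sequencing.

## The problem

16S-seq profiles bacterial communities by amplifying hypervariable regions of
the 16S rRNA gene with broad-range universal primers. In plant samples those
primers also amplify the host's mitochondrial and chloroplast 16S rRNA genes
— organelles are of prokaryotic ancestry — and the host fraction can reach
99% of reads, drowning out the microbiota. One remedy is to cleave the host
amplicons with Cas9 between the two PCR steps of library construction:
cleaved fragments do not amplify in the index PCR and vanish from the
library. The catch is guide design: the guide must cut the host 16S gene
while sparing the millions of closely related bacterial 16S sequences it is
supposed to leave alone.

`cas16s` implements that design problem end to end:

1. **Guide enumeration** — every 20-bp protospacer on the host gene that
   precedes a 5′-NGG-3′ PAM, on both strands.
2. **Off-target screening** — every 20-mer flush against an NGG or NAG PAM
   in a prokaryotic 16S reference set is aligned to each guide by anchored
   global alignment, and classified: a site is a potential off-target when,
   with T = 4 for NGG and T = 2 for NAG,

   * total M/D/I edits < T, **or**
   * total edits == T with every edit outside the seed region (the 12 guide
     positions adjacent to the PAM), and
   * the PAM-adjacent guide base aligned as a match (no mismatch/gap at the
     last nucleotide).

   Guides are ranked by the number of reference sequences carrying at least
   one qualifying site; a guide passes with fewer than 3,300 off-targets
   (0.1% of a 3.36M-sequence reference collection).
3. **Amplicon intersection** — in-silico PCR with degenerate (IUPAC)
   universal primers determines which guides lie inside the product of a
   given primer pair and are therefore usable with it.
4. **Depletion simulation** — an expected-value digestion model: member
   fractions are reweighted by survival, `f_i' = f_i (1−e_i) / Σ f_j (1−e_j)`,
   with multinomial read sampling on top to emulate rarefied OTU tables.

## Worked example

Design guides against a synthetic host gene and scan them against a
synthetic reference set that carries three planted near-matches (2 edits,
outside the seed) of one guide:

```python
from cas16s import synthetic_16s_gene, write_fasta, generate_reference_db, PlantSpec

host = synthetic_16s_gene(seed=7, length=1500, seq_id="host_mt_16S")
write_fasta([host], "host.fa")
# plant 3 sequences carrying a 2-edit off-target site of one guide
guide = "CTGAGCTTTGAGCTACTGAT"   # an enumerated guide of this gene
refs, _ = generate_reference_db(50, 300, [PlantSpec(guide, 2, frozenset({14, 18}))] * 3, seed=9)
write_fasta(refs, "refs.fa")
```

```console
$ cas16s design --host host.fa --out guides.tsv
157 guide sites
$ head -3 guides.tsv
guide_id  source_id    strand  start  end  protospacer           pam
gRNA28    host_mt_16S  +       8      28   ACCTTACTATACTCCCGCTC  CGG
gRNA29    host_mt_16S  +       9      29   CCTTACTATACTCCCGCTCC  GGG
$ cas16s scan --guides guides.tsv --refs refs.fa --out report.tsv
scanned 157 guide(s) against 50 reference(s)
$ tail -1 report.tsv
gRNA906   CTGAGCTTTGAGCTACTGAT  3  0  3  157  True
```

The planted guide ranks last (rank 157) with exactly its 3 planted
off-target sequences (`n_offtargets_ngg = 3`); every other guide has 0–1
chance hits and ranks above it. `passes_cutoff` is still `True` because 3 is
far below the 3,300 default cutoff. Other subcommands: `pcr` (in-silico
amplicons), `compatible-guides` (guides inside an amplicon), `rank`,
`simulate refdb` / `simulate digest`, and `run` (the whole workflow from one
TOML config, with a reproducibility manifest). An example universal-primer
config ships in `examples/primers.toml`.

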