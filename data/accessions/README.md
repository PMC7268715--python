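# Reference accessions (not redistributed)

Place the following FASTA files here to enable the accession-dependent
acceptance tests (see the README section "Reproducing the results"):

| file | contents |
|---|---|
| `rice_mt_16S.fasta` | rice (Nipponbare) mitochondrial 16S rRNA gene, one record |
| `rice_cp_16S.fasta` | rice (Nipponbare) chloroplast 16S rRNA gene, one record |
| `AB658673.fasta` | soil bacterial 16S rRNA gene, NCBI accession AB658673 |

The rice organelle genes come from the Nipponbare reference genome (NCBI
genome 10); extract the annotated 16S rRNA (rrn18/rrn16) gene regions from
the mitochondrial and chloroplast genome records. Each file should hold a
single FASTA record of roughly 1.5 kb.
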