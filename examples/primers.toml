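# Standard published universal 16S rRNA gene primer sequences (literature
# consensus versions of the commonly used names).  Supply your own file in
# this format if your protocol uses different variants.

[primers.27F]
sequence = "AGAGTTTGATCMTGGCTCAG"
orientation = "forward"

[primers.338R]
sequence = "TGCTGCCTCCCGTAGGAGT"
orientation = "reverse"

[primers.515F]
sequence = "GTGYCAGCMGCCGCGGTAA"
orientation = "forward"

[primers.806R]
sequence = "GGACTACNVGGGTWTCTAAT"
orientation = "reverse"

[primers.799F]
sequence = "AACMGGATTAGATACCCKG"
orientation = "forward"

[primers.1193R]
sequence = "ACGTCATCCCCACCTTCC"
orientation = "reverse"

[primers.1114F]
sequence = "GCAACGAGCGCAACCC"
orientation = "forward"

[primers.1392R]
sequence = "ACGGGCGGTGTGTRC"
orientation = "reverse"
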