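# Methods

## The design problem

A guide RNA for host-16S depletion must direct Cas9 to cleave the host
organelle 16S rRNA amplicon while leaving bacterial 16S amplicons intact.
Because organelle 16S genes are homologous to bacterial ones, the design is
an off-target screening problem at unusual stringency: the "genome" being
screened is a reference collection of prokaryotic 16S sequences, and the
ideal guide has zero qualifying sites in it.

## Guide enumeration

Every 20-nt window of unambiguous ACGT immediately 5′ of a PAM is a guide
site. The PAM pattern defaults to 5′-NGG-3′ (SpCas9); pattern positions are
interpreted as *guarantees* — a template base qualifies only if its IUPAC
set is a subset of the pattern position's set, so a degenerate template base
can satisfy N but never a fixed G. Both strands are scanned (the amplicon is
double-stranded), windows containing degenerate bases are skipped rather
than expanded (guides must be synthesizable unambiguous oligos), and all
overlapping sites are reported. Guide ids are `<prefix><p>` with `p` the
1-based plus-strand coordinate of the PAM-proximal protospacer base; ids
colliding across strands get a deterministic `.2` suffix. This naming is a
fixed convention of this package — positional names in the style of
published guide names, but no claim is made that the numbering matches any
particular external labelling.

## Off-target model

Candidate sites are all 20-mers flush against NGG (canonical) or NAG
(weakly recognized) PAMs in the reference, both strands. The PAM class is
decided by the two fixed trinucleotide positions; the N position is
unconstrained. Reference windows containing degenerate bases are skipped by
default; a strict mode instead keeps them with the degenerate base replaced
by a sentinel that matches nothing, i.e. counts ambiguity as a guaranteed
mismatch.

### Anchored lexicographic alignment

Guide and candidate are compared PAM-proximal-last under unit cost per
mismatch, insertion, and deletion (M/D/I equivalent, no affine gaps):

* the terminal (PAM-adjacent) column is anchored: the candidate extraction
  places the 20-mer flush against the PAM, so the last guide base is
  compared positionally and must match (`anchored_match`); this implements
  "no mismatch/gap at the last nucleotide" exactly and removes alignment
  ambiguity at the anchor;
* the remaining 19-vs-19 problem is a free global alignment;
  `total_edits` is its minimum edit distance;
* `seed_edits` is the minimum number of edits assigned to seed positions
  (guide positions 1..12 from the PAM) over **all** co-optimal alignments.

Edit-to-position assignment: a mismatch or deletion is charged to the guide
position it consumes; an insertion (gap in the guide) to the adjacent
PAM-proximal guide position (an insertion flush against the anchor is
position 1, inside the seed). The lexicographic objective (minimize total,
then seed) is computed in one dynamic program by packing cost pairs as
`total*64 + seed` — seed counts never reach 64, so the numeric minimum is
the lexicographic minimum. Minimizing seed edits over co-optimal alignments
means the "all edits outside the seed" rescue fires whenever any optimal
alignment permits it: the conservative (maximum-sensitivity) reading for a
depletion tool, where a missed off-target silences a real taxon.

Two implementations share this definition: a scalar reference
(`align_guide_candidate`) and a numpy-vectorized batch used by the counting
pipeline; the test suite checks them against each other, against an
independent edit-distance library on the anchored subproblem, and against
exhaustive alignment-path enumeration for the seed statistic.

### Classification

With T = 4 (NGG) or T = 2 (NAG): a site qualifies iff the anchor matches
and (`total_edits < T` or (`total_edits == T` and `seed_edits == 0`)). The
threshold case with *any* edit in the seed is rejected — the rescue clause
is read as all-edits-outside-seed; partial rescue is not granted.

### Counting, exclusions, ranking

`n_offtargets` counts distinct reference *sequences* with ≥ 1 qualifying
site (the quantity that matters for depletion risk is how many taxa could
be cut); a `count_sites` switch reports per-site totals instead. A sequence
with at least one NGG-qualifying site is tallied under the NGG column, one
with only NAG sites under NAG, so the two columns always sum to the total.
References listed in the exclusion set (host-organelle homologs, e.g.
chloroplast records when scoring chloroplast guides) and any reference
whose id equals the guide's source are skipped. Guides are ranked by
ascending `n_offtargets` with guide id as the deterministic tie-break. The
pass cutoff defaults to the absolute value 3,300, with a fractional
alternative (0.1% of the post-exclusion reference count).

### Prefilter

The k-mer prefilter drops candidates that provably cannot qualify, by the
q-gram bound: strings of length 20 within edit distance e share at least
`(20−k+1) − e·k` k-mers. The filter is keyed to the classification edit cap
(e = `max_edits_ngg`, word length k = 4 by default, so survivors share ≥ 1
four-mer with the guide). This is strictly lossless for the final calls:
any qualifying site has at most 4 edits, hence identity ≥ 0.8 — well above
the 0.6 identity floor that a search heuristic would use, which a q-gram
bound at this word length could not certify anyway. Losslessness, not a
particular identity floor, is the contract; the pipeline is verified to
produce bitwise-identical reports with the filter on and off, and the
filter can be disabled (`--no-prefilter`).

## In-silico PCR

Primer matching is positional IUPAC intersection (R matches A or G, N
matches anything), mismatches optional (default 0) and indels never —
primer-template bulges do not amplify usefully. Forward primers scan the
plus strand; reverse primers scan as their reverse complement. Products are
primer-inclusive (the coordinates and length include both footprints, as
product lengths are read on a gel), capped by a maximum product length; all
(fwd, rev) site pairs are reported, with overlapping products flagged
rather than silently resolved. A guide is compatible with an amplicon only
if protospacer *and* PAM lie entirely inside the product, on either strand.

## Synthetic data

`generate_reference_db` produces seeded uniform-random ACGT sequences with
planted candidate sites: each `PlantSpec` applies substitutions at chosen
guide positions (1 = PAM-adjacent) and appends a PAM of the chosen class.
Planted substitutions use a fixed transversion map (A↔C, G↔T), making the
planted site a pure function of (guide, positions) — a property the test
fixtures rely on, since hand-derived expected classifications are only
well-defined when the planted site is deterministic. A spec demanding an
edit at position 1 together with an expected off-target call is rejected:
the anchored rule makes it impossible by construction.

Two caveats the fixtures account for, and which matter when reasoning about
planted truth in general: an optimal alignment may *compress* a planted
edit cluster (e.g. edits spread across a repetitive stretch can be
explained by fewer edits), so "n planted edits" is an upper bound, not the
alignment's edit count; and windows *shifted* relative to a planted
near-identical site can themselves qualify when the neighbouring bases
happen to form a PAM. Fixture guides are therefore fixed sequences verified
once against an exhaustive path-enumeration oracle, and negative
expectations are asserted against the planted site itself rather than
whole-sequence absence.

What the generator does *not* emulate: real 16S phylogenetic structure
(uniform-random backgrounds are far less self-similar than a real 16S
collection, so absolute off-target counts on synthetic sets say nothing
about counts on a real reference), PCR amplification bias, chimeras, or
sequencing error. Passing tests demonstrate the correctness of the
classification arithmetic and the counting pipeline, not field performance
of any particular guide.

## Digestion model

Digestion is deterministic at the fraction level: member i with cleavage
efficiency e_i keeps survival weight `f_i(1−e_i)`, renormalized. For a
two-member community with host fraction h this is `h′ = h(1−e)/(1−he)`.
Complete depletion (zero total survival) is an error, mirroring the fact
that a fully cleaved pool yields no library. Stochasticity enters only via
`sample_counts`, a seeded multinomial draw emulating a rarefied OTU table —
separating expectation from sampling keeps the model's invariants exact
(normalization, monotonicity in e, closed form) and testable to 1e−12.
Gel-readout or sequencing fractions are ensemble quantities, which is why
an expected-value model is the right level of description.

## Numerical and design choices

* All randomness flows through seeded generators (`numpy.random.default_rng`
  and `random.Random`); fixtures and outputs record their seeds.
* Problem sizes in the test battery and acceptance script: oracle
  equivalence uses 20 seeded instances of 50 guides × 200 references of
  150 nt; planted recovery uses 100 seeded sets of 11 plant specs in 120-nt
  backgrounds. These sizes exercise every code path (both PAM classes, both
  strands, hits and misses, prefilter survivors and drops) while keeping the
  battery fast enough to run routinely.
* Sequence-unit counting (not site counting) is the default because a
  depletion design cares about how many distinct taxa are at risk; the
  per-site mode exists for auditability.
* Reference-scale screening (millions of sequences) is supported by the
  streaming candidate extractor and the vectorized aligner but is
  intentionally not part of the test battery; results on a given reference
  release depend on that release's composition.

## Known limitations

* The aligner is specialized to 20-nt guides (the packed-cost dynamic
  program assumes the 19+1 anchored layout); other guide lengths would need
  a generalized DP.
* NAG sites are subjected to the same anchored-match rule as NGG sites; the
  classification rule set treats the anchor as universal.
* Primer thermodynamics (Tm, 3′-end stability) are out of scope; primer
  matching is purely combinatorial.
* The digestion model ignores inter-template amplification bias and
  chimera formation.
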