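# Methods

## The substitution model

A DGR reverse transcriptase copies the template repeat (TR) RNA with
misincorporation confined to adenine positions; the cDNA replaces the
variable repeat (VR) in the target gene. An ungapped TR/VR alignment column
therefore falls into one of four classes:

- **match** — identical bases;
- **A_sub** — TR = A, VR ≠ A (the DGR signal);
- **B_sub** — TR ∈ {C,G,T} and VR differs (background, "B→B"; in natural
  data these arise from ordinary replication errors or drift);
- **ambiguous** — either base is N, or the column contains a gap.

These four counts always partition the alignment length; every downstream
statistic is a function of this partition plus the reading frame.

## Repeat-pair detection

`find_repeat_pairs` is a seed-and-extend scan specialised to the adenine
asymmetry:

- **Seeds** are exact k-mers (k = 12 by default) containing no adenine.
  Under the pure adenine model an A-free stretch of the TR survives
  retrohoming unchanged, so a shared A-free 12-mer is the one exact match
  detection can rely on regardless of how heavily the adenines mutated. A
  12-mer over {C,G,T} occurs by chance at ~3 % of positions, keeping the
  index small. k is configurable; repeats whose A-free stretches are all
  shorter than k are not found (documented limitation).
- **Extension** is gapless along the seed diagonal with match +1,
  mismatch 0 when either copy has A, −2 otherwise, terminated by an X-drop
  rule (default 20) and trimmed to the earliest maximal-scoring extent, so
  score-neutral adenine columns at the edge are not absorbed. During
  extension the TR copy is still unknown, hence the symmetric "either copy
  has A" rule; the asymmetric attribution happens afterwards.
- **TR designation**: the copy carrying adenine in ≥ 80 % of mismatched
  columns (configurable) is the template. If neither copy qualifies the
  pair is discarded — this is what rejects VR1-vs-VR2 pairings, whose
  mismatch adenines split roughly evenly between the copies. For pairs
  with no mismatches at all the leftmost copy is called TR by convention.
- **Filters**: extended length within [min_len, max_len] (defaults
  100–150 bp), B→B fraction ≤ 0.1, and at least `min_A_sub` = 3 adenine
  substitutions. Overlapping reports (≥ 90 % reciprocal overlap of both
  intervals) are merged keeping the highest score.
- **Strands**: the scan runs on the forward sequence, on its reverse
  complement (a minus-strand cassette is adenine-asymmetric only when read
  on the minus strand), and across the two (inverted pairs). Circular
  genomes are scanned with an origin-spanning overhang; a repeat that
  itself crosses the origin is not representable and is skipped.

The search is deliberately ungapped: natural TR/VR alignments show
substitutions only, and a pair containing an indel is simply not detected
rather than mis-scored.

## Cassette assembly

Pairs whose TR intervals overlap reciprocally by ≥ 90 % form one cassette
with multiple targets. The target ORF is the longest ORF fully containing
the VR; the VR's position class is *five_prime* / *three_prime* when its
midpoint lies in the first / last third of the gene, else *internal*. The
RT gene is the nearest ORF labeled "reverse transcriptase" within 5 kb of
the TR (RT discovery by homology is out of scope — labels come from the
user's annotation, a GenBank file, or the simulator), likewise the
accessory Avd gene. The VR's frame offset, `(vr_start − orf_start) mod 3`
on the coding strand, is inherited by the TR for translation: the TR
itself is non-coding, but its hypermutation potential only makes sense in
the frame of the gene it rewrites.

## Amino-acid analysis

`substitution_profile` translates TR and VR (genetic code table 11 —
standard for gut phages and their bacterial hosts; configurable) over
codons fully contained in the aligned span; codons touching an ambiguous
or gap column are skipped. It reports positionwise residue substitutions
(the same position counted once per pair, not unique residues), a subtotal
restricted to codons free of B→B changes, and a category spectrum of the
incoming residues with disjoint classes: aromatic {F,W,Y}, negative {D,E},
positive {K,R,H}, cysteine {C}, hydrophobic non-aromatic {A,V,L,I,M,P,G},
hydrophilic uncharged {S,T,N,Q}. Histidine is counted as positively
charged rather than aromatic to keep the partition disjoint; the mapping
is overridable. Cys-gaining substitutions are visible in the cysteine
category; no structural (disulfide-distance) check is attempted.

`achievable_residues` enumerates, for a codon, all variants obtained by
substituting each adenine independently with A/C/G/T, translates them and
returns the distinct residues (stops excluded but flagged). For AAC/AAT
this gives 15 residues — all but Gln, Met, Lys, Glu, Trp — which is why
Asn-codon-rich TRs maximise the explorable sequence space.
`codon_position_bias` aggregates which base replaced the adenine at codon
positions 1 and 2 of AAC/AAT codons, with the position-1/position-2 A→C
ratio reported (0/0 → NA); natural spectra show a strong position-1
preference for A→C.

## Pairwise identity

`pairwise_identity` uses global Needleman–Wunsch (Biopython's
`PairwiseAligner`): +1/−1 for nucleotides, BLOSUM62 for proteins, gap open
−10 / extend −0.5. Identity = identical columns / full alignment length,
gaps included; the input pair is ordered canonically before aligning so
the value is exactly symmetric. Published identity figures computed with
other tools use unstated conventions and are not expected to reproduce
exactly under this definition.

## TR/VR alignment

Equal-length repeats are paired positionally (retrohoming preserves the
template's length). Unequal lengths (ratio within [0.5, 2]) use a
semi-global dynamic program placing the shorter sequence inside the
longer: match +1, mismatch at a TR adenine 0, other mismatch −2, gap −4,
free end gaps in the longer sequence only, leftmost co-optimal placement.
Columns outside the overlap are excluded from the span; uncovered TR
adenines still count toward `n_tr_adenines` but not the covered total.

## Motif profiling

`build_profile` computes per-column residue frequencies (20 residues +
gap) over an aligned set and calls a column conserved when one residue
reaches the threshold frequency (default 1.0, i.e. strictly invariant
columns — the convention for the tentaclin Cterm-Ig signature; whether a
published signature derives from a small curated set or a larger
homolog set only changes this threshold, which is why it is exposed).
`scan_protein` slides the profile ungapped over the last `tail_window`
(default 100) residues; the score is the mean per-column log-odds versus a
uniform 1/20 background with a small pseudocount (0.01), and a protein
carries the signature iff some offset matches every conserved column
exactly. The expected chance-match rate for a c-column strict signature is
`1 − (1 − 20^−c)^offsets` per protein, which the test suite checks by
Monte Carlo. MSA construction itself is out of scope: profiles are learned
from user-supplied alignments, and `tests/data/cterm_ig_synthetic_29.afa`
is a synthetic 29-sequence stand-in (7 planted invariant columns among
random background) used by the tests.

## The simulator

`simulate_genome` emits a linear genome (default 30 kb) with the canonical
layout — filler, RT gene (300 codons), Avd gene (130 codons), non-coding
TR, target 1 (≥ 570 codons, VR in the 5′ third), target 2 (VR ending a few
codons before the stop, 3′ third) — and a truth record of every interval
and substitution. Choices that mirror natural cassettes, and their
consequences:

- **TR layout**: adenines sit predominantly in AAC/AAT codon pairs in the
  target frame (`n_adenine_pairs`, default 12, plus `n_lone_adenines`,
  default 1 → 25 adenines in 120 bp, the nd4-like configuration; the
  nd12-like preset gives 28). Spacer codons are adenine-free, the first
  codon and the last five codons (the segment adjacent to the IMH*
  initiation sequence) are adenine-free — which also guarantees the
  A-free 12-mer that seeds detection.
- **Mutation**: each TR adenine mutates in each VR independently with
  probability `p_sub` to a base drawn from `base_weights` over {C,G,T}
  (optionally per codon position); each non-adenine site mutates with
  probability `q_background` to a uniformly chosen different base. With
  `forbid_stop` (default on) any VR codon that would read as a stop in the
  target frame is resampled (≤ 100 attempts, then a deterministic
  stop-free fallback), reflecting that target proteins must stay
  functional.
- **Boundaries**: the two codons flanking each VR (and the 6 bp flanking
  the TR) are drawn to mismatch base-for-base and contain no adenine.
  Homology between TR and VR terminates, by definition, at the declared
  repeat boundary — were the flanks allowed to match, the true repeat
  would simply be longer than declared — and this makes exact interval
  recovery a well-posed target for the detection tests.
- `expected_spectrum` gives the closed-form binomial moments of the
  per-VR substitution counts for comparison with Monte-Carlo runs.

What the simulator does **not** emulate: indels between TR and VR,
cassettes split across contigs, selection acting on the VR repertoire
beyond stop avoidance, multiple sequential retrohoming events, GC-content
structure of real phage genomes, or sequencing artefacts. Tests passing on
simulated data therefore validate the bookkeeping and the statistical
machinery, not detection sensitivity on diverged natural repeats with
indels.

## Problem sizes used in validation

The validation experiments use 50 simulated genomes (seeds 0–49) for
ground-truth recovery, 500 dual-target genomes (1000 retrohoming events)
for binomial consistency, 100 random 1 kb genomes for the ORF-calling
oracle, 100 random repeat pairs for the alignment-DP oracle, and 10,000
random proteins for the motif null scan; the whole suite runs in well
under a minute on one core.

## Numerical and tie-breaking conventions

Coordinates are 0-based half-open internally, 1-based inclusive in every
report. Detection trims to the *earliest* maximal-scoring extension;
semi-global alignment prefers diagonal moves and the leftmost co-optimal
placement; identity canonically orders its inputs. Ambiguous (N) columns
never count as substitutions. Reruns of any pipeline configuration on the
same inputs are byte-identical; simulation is deterministic given its
seed.

## Known limitations

- Gapped TR/VR pairs are not detected (ungapped scan by design).
- Repeats crossing a circular genome's origin are skipped.
- RT/Avd assignment relies on annotation labels, not homology search.
- Conservation threshold 1.0 is brittle to a single misaligned sequence in
  the input MSA; lower it for noisy alignments.
- GenBank CDS features with more than two location segments are skipped
  with a warning.
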