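# dgrscan

Detection and quantitative analysis of **diversity-generating retroelements
(DGRs)** in phage and prophage genomes.

A DGR cassette couples an error-prone reverse transcriptase (RT) to a
non-coding **template repeat (TR)** of ~100–150 bp. During retrohoming the
TR's RNA is reverse-transcribed with misincorporation restricted to adenine
positions and the product overwrites a **variable repeat (VR)** inside a
target gene — typically a receptor-binding protein, where the VR encodes a
surface β-hairpin. Some cassettes carry *two* target genes: one with the VR
near the gene's 5′ end and one with the VR at its 3′ end. `dgrscan` finds
such repeat pairs, assembles them into cassettes, and quantifies the
hypermutation they produce.

## What it computes

- **Repeat-pair detection.** Exact adenine-free *k*-mer seeds (an A-free
  stretch of the template survives retrohoming unchanged) are extended
  without gaps under an asymmetric scoring model: match +1, mismatch at an
  adenine column 0, any other mismatch −2. A pair of loci is a TR/VR
  candidate when its length is in range, the background (non-adenine,
  "B→B") mismatch fraction is small, and one copy — designated the TR —
  carries adenine in ≥ 80 % of the mismatched columns.
- **Substitution spectra.** Each TR/VR alignment is partitioned into match,
  A-substitution (TR = A, VR ≠ A), B→B and ambiguous columns; the repeats
  are translated in the frame the VR occupies in its target gene, giving
  per-codon and per-residue substitution lists, amino-acid category spectra
  (aromatic, charged, …) and the codon-position bias of A→C changes inside
  AAC/AAT (Asn) codons.
- **Reachable residues.** For any codon, the set of amino acids obtainable
  when only its adenines mutate. For the Asn codons AAC/AAT this is 15
  residues — every amino acid except Gln, Met, Lys, Glu and Trp.
- **Motif profiling.** Per-column conservation profiles over aligned domain
  sets (e.g. the C-terminal Ig anchor domain shared by tentaclin-family
  receptor-binding proteins) and an ungapped scanner that asks whether a
  protein's C-terminal tail carries the invariant-residue signature.
- **Simulation.** A forward simulator emits genomes with the canonical
  cassette layout (RT, accessory Avd gene, TR, dual targets) and a ground
  truth record of every substitution, so the whole pipeline is testable
  without any external data.

## Worked example

Simulate an nd4-like genome (25 TR adenines, per-adenine substitution
probability 0.5) and run the full pipeline on it:

```sh
dgr simulate --preset nd4like --seed 42 --out nd4sim.fasta \
    --truth truth42.json --orfs-out orfs42.tsv
dgr run --in nd4sim.fasta --orfs orfs42.tsv --outdir out --seed 42
```

which prints

```
wrote sim_42 (30000 bp) to nd4sim.fasta
1 cassettes across 1 genomes -> out
```

`out/cassettes.tsv` then contains (1-based coordinates):

```
# genome_id  tr_start  tr_end  vr_start  vr_end  strand  target_orf                        vr_position_class  frame_offset  n_A_sub  n_B_sub
sim_42       5875      5994    7676      7795    +       tentaclin-like target protein 1   five_prime         0             13       0
sim_42       5875      5994    11919     12038   +       target protein 2                  three_prime        0             14       0
```

One cassette was found whose 120 bp TR (positions 5875–5994) feeds two VRs:
one in the 5′ third of target 1 with 13 adenine substitutions, one in the
3′ third of target 2 with 14 — and zero B→B substitutions, as expected with
the background rate at 0. `out/profile.tsv` adds the amino-acid level: of
the 25 TR adenines all are covered by each VR, and the 13/14 nucleotide
changes translate into 10 residue substitutions in each target protein,
split by category (e.g. 3 aromatic and 1 positively charged in target 1).
`out/aa.tsv` lists every substituted residue and `out/summary.json` the
whole run in machine-readable form.

The library mirrors the CLI: `find_repeat_pairs`, `assemble_cassettes`,
`align_tr_vr`, `substitution_profile`, `achievable_residues`,
`build_profile` / `scan_protein`, and `simulate_genome` are all importable
from `dgrscan`.

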