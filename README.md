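# mitoforms

Multipartite-structure analysis for circular plant mitochondrial genomes.

Seed-plant mitogenomes are deposited as a single "master circle", but the
molecule population in living tissue is usually a mixture of alternative
arrangements: pairs of near-identical repeats recombine, and a crossover
between **direct** repeats splits one circle into two (or fuses two back
into one), while a crossover between **inverted** repeats flips the
intervening segment. `mitoforms` implements this analysis end
to end — modelled on the sweet potato (*Ipomoea batatas*) mitogenome, a
270,304 bp master circle whose three direct repeat pairs generate a
polycyclic population — for people working on organelle genome
structure, cytoplasmic male sterility, or organelle phylogenomics:

* **Repeat discovery** — microsatellites under MISA rules (thresholds
  `1-10 2-6 3-5 4-5 5-5 6-5`), maximal exact dispersed repeats
  (forward / palindromic / reverse / complement), and scored paired repeats
  from BLAST-like local self-alignment of the circle (seed-and-extend with
  a Karlin–Altschul e-value, E = K·m·n·e^(−λS)).
* **Conformation algebra** — applies fission / fusion / inversion events
  through repeat pairs and enumerates every conformation reachable from the
  master circle, deduplicated by rotation- and strand-invariant canonical
  form. Fission through direct copies starting at s₁ < s₂ on a circle of
  length L yields circles of s₂−s₁ and L−(s₂−s₁) bp; total length is
  conserved by every event.
* **Long-read evidence** — for each repeat pair, four templates
  (ref1 = up₁·R₁·down₁, ref2 = up₂·R₂·down₂, and the recombinants
  rec1/rec2 with downstream flanks exchanged, flanks of 1000 bp on the
  circle); a long read supports the unique template whose repeat ± anchor
  window it spans at sufficient identity. Recombination is called
  supported when ≥ 2 reads back a recombinant template.
* **RNA-editing calling** — pileups over coding sequences (internal edlib
  mapper or SAM), sites called where depth > 10×, with editing efficiency
  = edited/(edited+reference), the binomial MLE; substitution types
  reported in transcript space (C-to-U etc.).
* **Chloroplast DNA transfer** — homologous fragments between the
  mitogenome and plastome (word size 7, E ≤ 10⁻⁶), with the transferred
  share of the genome computed from the union of mitochondrial intervals.
* **Synthetic data** — a fully deterministic generator for circular
  genomes with planted repeat pairs, nanopore-like reads from weighted
  conformation mixtures, RNA-seq with planted edits at specified
  efficiencies, and plastid tracts inserted into the mitogenome — each
  with a ground-truth manifest.

## Worked example

Simulate a 30 kb circle carrying one 150 bp direct repeat pair, detect the
pair, and enumerate the reachable conformations:

```sh
mitoforms simulate-genome --seed 13 --length 30000 \
    --repeat 150,100,direct,6000,20000 --out g.fa
mitoforms repeat-pairs --fasta g.fa --out pairs.tsv
mitoforms conformations --fasta g.fa --pairs pairs.tsv --out conf.tsv
mitoforms report --pairs pairs.tsv
```

`pairs.tsv` holds the detected pair (the maximal local alignment extends a
few bases past the planted 150 bp copy, picking up chance matches):

```
name	identity	length	position1	position2	evalue	type
R1	98.10	158	6000-6157	20000-20157	7.33E-74	direct
```

and `conf.tsv` the two reachable states — the master circle and the
two-circle fission state whose sizes are the start-to-start distance
(14,000 bp) and its complement (16,000 bp), with total length conserved:

```
state_id	repeats_applied	n_circles	sizes_csv	total_bp
S1	-	1	30000	30000
S2	R1	2	16000,14000	30000
```

Sampling long reads from the master alone
(`mitoforms simulate-reads --seed 5 --fasta g.fa -n 120 --length-mean 4000
--out reads.fq` followed by `mitoforms recomb-evidence`) classifies every
spanning read to a reference template and none to a recombinant one, so
the pair is reported `unsupported` — recombination requires recombinant
molecules in the read mixture, not just the repeat.

The same stages are available as a library (`mitoforms.find_repeat_pairs`,
`mitoforms.apply_recombination`, `mitoforms.classify_spanning_reads`, …)
returning typed records rather than TSV rows.

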