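# vipseq

Detection and absolute quantification of spontaneously induced prophages
from virion sequencing data.

Many bacteria carry prophages — phage genomes integrated in the chromosome —
and a fraction of a culture's cells spontaneously induce them, releasing
virions into the supernatant. `vipseq` analyses sequencing libraries made
from that virion DNA (DNase-treated, so chromosomal DNA is removed) mapped
back to the lysogen's own assembly:

* **Detection.** An induced prophage shows up as an island of high read
  coverage over its integrated copy. Because the excised phage genome is
  circular, read pairs whose fragment crossed the circular junction map as
  outward-facing discordant pairs at the island's edges, and reads that
  themselves cross the junction map soft-clipped with the clip boundary
  sitting exactly on *attL* or *attR*. `vipseq` segments coverage islands
  and then refines boundaries to the exact base from this junction evidence.
* **Quantification.** The eluted DNA mass is partitioned among the detected
  prophages by their mapped-read fractions and converted to absolute titres:

  titre = m_DNA · N_A / (M_nt · L_prophage) · (r_pp / r_tot)

  with m_DNA the eluted DNA mass per 1 mL of culture, N_A Avogadro's
  constant, M_nt = 617.96 g/mol/bp the average molar mass of a DNA base
  pair, L_prophage the prophage length, and r_pp/r_tot the fraction of
  mapped reads in the prophage region. The same arithmetic run backwards
  gives the method's detection limit and, against a CFU count and burst
  size, a spontaneous induction rate per cell.
* **Benchmarking, phagotypes, protection.** Utilities to score in-silico
  prophage predictions against experimentally active prophages, cluster
  active prophages by whole-genome similarity, group strains into
  *phagotypes* by their prophage-cluster content, and test whether strains
  sharing a phagotype are protected from each other's phages in plaque
  assays.
* **Simulation.** A truth-tracked read simulator (lysogen genome, virion
  read pairs with exact junction geometry, optional lateral-transduction
  coverage gradients) used by the test suite as an oracle and available
  from the CLI.

## Worked example

Simulate a lysogen with two active prophages, detect them, and quantify:

```sh
cat > sim.yaml <<EOF
genome_len_bp: 150000
total_read_pairs: 15000
prophages:
  - {length_bp: 20000, gc: 0.45, titre: 1.0e7, insertion_pos: 40000}
  - {length_bp: 30000, gc: 0.55, titre: 4.0e6, insertion_pos: 110000}
EOF

vipseq simulate --config sim.yaml --seed 21 --out-dir sim
vipseq detect   --genome sim/genome.fasta --alignments sim/reads.truth.sam --out-dir det
vipseq quantify --calls det/calls.bed --alignments sim/reads.truth.sam \
                --metadata sim/sample_metadata.tsv --out-dir quant
vipseq limit
```

Output (titres match the configured 1e7 and 4e6 exactly; boundaries are
base-exact, see `det/calls.tsv`):

```
prophage_1	1e+07 virions/mL
prophage_2	4e+06 virions/mL
aggregate	1.4e+07 virions/mL
detection limit: 7.2e+05 virions/mL
```

```
$ cat det/calls.tsv
genome_id	start_1based	end_1based	label	length_bp	support_count	mean_depth	confidence	gc_relative
sim_chrom	40001	60000	prophage_1	20000	222	139.03805	junction	-0.054...
sim_chrom	130001	160000	prophage_2	30000	82	54.8522	junction	0.044...
```

Other subcommands: `vipseq compare` (score predictions against active
prophages), `vipseq phagotype` (clustering, phagotypes, protection
statistics). All stages accept `--help`.

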