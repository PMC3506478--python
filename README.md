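# evosite

Site-level molecular-evolution analyses for ortholog alignments:

- **RCA** — reverse conservation analysis: empirical-Bayes per-column rate
  estimation under a discrete-gamma prior (JTT, K=16), normalized S scores
  (mean 0, SD 1; higher = more variable), sliding-window W means (n=7) and
  0.5-SD threshold region calling in reference-residue coordinates.
- **REL** — random-effects-likelihood positive-selection scan: constrained
  reversible nucleotide models per gene, an MG94/GY-style codon model with a
  3 dN x 3 dS class grid fitted by maximum likelihood, per-site
  empirical-Bayes posteriors, Bayes factors, and strong (BF >= 50) / weak
  (10 <= BF < 50) site classification.
- **BGM** — co-evolution detection: joint ML ancestral codon reconstruction,
  binary site x branch non-synonymous substitution maps (>= 3 count filter),
  order-based structure MCMC over networks with in-degree <= 2, posterior
  edge calling at 0.5 and connected-component grouping.
- **phylo** — Felsenstein pruning over arbitrary state spaces (4/20/61),
  JTT ML distances, BIONJ tree construction, branch-length optimization and
  bootstrap support.
- **simulate** — seeded generators for Yule/star trees, gamma-rate protein
  alignments, codon alignments with per-site (dN, dS) classes, and coupled
  co-evolving site pairs, all with truth tables.

## CLI

```bash
evosite init --out run.yaml           # write a config with all defaults
evosite all run.yaml                  # RCA + REL + BGM + joined site report
evosite rca run.yaml --window 7 --threshold 0.5
evosite rel run.yaml --constraints chiJ --strong 50 --weak 10
evosite bgm run.yaml --min-nonsyn 3 --pp 0.5 --seed 1
evosite simulate codons --seed 1 --n-taxa 12 --n-sites 300 --out-prefix sim
```

The config names the inputs (FASTA protein and/or in-frame nucleotide
alignment; Newick tree or `build` for BIONJ + ML branch lengths), the
reference sequence for residue numbering, leading-trim sizes (residues/bp;
reported coordinates stay in untrimmed reference numbering), and per-stage
parameters. Outputs are TSV/JSON per stage plus a joined per-residue
`site_report.tsv`.

Nucleotide-model presets `chiJ`, `recA`, `dnaN` encode published
exchangeability-sharing schemes; `equal` and `gtr` are the usual extremes,
and custom schemes are accepted as mappings from the pairs
{AC, AT, CG, CT, GT} to `ref` (the A<->G reference rate) or shared
parameter names.

## Library sketch

```python
from evosite import seqio, rca, rel, bgm
from evosite.phylo import jtt_model, bionj, distance_matrix, optimize_branch_lengths

aln = seqio.read_alignment("protein.fasta", seqio.PROTEIN)
aln = seqio.trim_leading(aln, 36)
refmap = seqio.build_reference_map(aln, "Mg1")

D, labels = distance_matrix(aln, jtt_model())
tree = optimize_branch_lengths(bionj(D, labels), aln, jtt_model())

profile = rca.conservation_profile(aln, tree, jtt_model(), ref_map=refmap)
profile.regions          # [(start, end), ...] in reference numbering
```
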