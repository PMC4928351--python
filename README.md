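# ahekit

Anchored hybrid enrichment (AHE) is a target-capture strategy for
phylogenomics: tiled oligonucleotide probes hybridize to conserved exonic
"anchor" regions, pulling down genomic fragments whose variable flanks carry
most of the phylogenetic signal. `ahekit` implements the bioinformatic
workflow that turns raw paired-end capture reads into a partitioned
phylogenomic supermatrix, for systematists building AHE (or similar
target-capture) datasets and for methodologists who want each stage testable
in isolation:

- **probe/target design** — select gap-free, exon-boundary-free alignment
  regions with ≥ 6 taxa and a 120 bp window above 50% pairwise identity,
  mask high-copy regions by a 15-mer (Hamming-1 neighborhood) genome census,
  and tile 120 bp probes uniformly at 1.72× density;
- **read merging** — for every overlap degree *o* between read 1 and the
  reverse complement of read 2, compute the one-sided binomial tail
  P(X ≥ matches | o, 0.25); merge at the minimal-p overlap iff p < 10⁻¹⁰,
  reconciling mismatches by base quality (sum on match, difference on
  mismatch);
- **assembly** — seed reads onto probe-region references with spaced
  20-mers (every third base; ≥ 17/20 positional matches), confirm with
  ≥ 55 matches in the best 100 consecutive bases over all gap-free offsets,
  extend de novo through shared exact 60-mers to a fixed point, cluster
  reads via 60-mer co-occurrence, refine offsets (≤ 1 gap per read), and
  call consensus under a binomial error model (p = 0.1, α = 0.05) with
  IUPAC ambiguity codes and lowercase soft-masking below 5× coverage;
- **orthology** — drop consensus sequences from clusters with < 10 reads
  (low-level contaminants), then agglomerate homologs by ascending shared
  20-mer (consecutive + spaced) Jaccard distance, never joining clusters
  that would hold two sequences from one individual; clusters below 50%
  species occupancy are discarded;
- **alignment + trimming** — MAFFT (`--genafpair --maxiterate 1000`)
  followed by conserved-column flagging (modal character > 40%), masking of
  20 bp stretches with < 10 stable sites, and removal of columns with < 12
  unmasked bases;
- **supermatrix** — concatenation with a RAxML-style partition table,
  occupancy and parsimony-informative-site statistics, and a
  neighbor-joining sanity tree on pairwise p-distances (ML inference is
  deliberately left to external tools).

A first-class synthetic-data module generates ground-truthed inputs — a
random ultrametric species tree, loci with a conserved anchor and faster
flanks, ~150–350 bp fragments sequenced as PE150 reads with per-base Phred
qualities, random contaminants and planted gene duplications — so the whole
pipeline can be audited against planted truth without any downloads.

## Worked example

```python
from ahekit.simulate import SimulationConfig
from ahekit.pipeline import run_pipeline, evaluate_recovery, rf_distance
from ahekit.supermatrix import stats

cfg = SimulationConfig(seed=11, n_taxa=8, n_loci=30,
                       base_error_rate=0.003, contam_fraction=0.01)
result = run_pipeline(cfg)

recovery, _ = evaluate_recovery(result)
print(f"haplotype recovery: {recovery:.3f}")
print(stats(result.matrix))
print("RF to true tree:",
      rf_distance(result.nj_newick,
                  result.truth.tree.as_string(schema="newick")))
```

Output:

```
haplotype recovery: 1.000
{'n_taxa': 8, 'n_loci': 30, 'n_sites': 20678, 'n_informative': 5116,
 'pct_missing': 2.12061127768643}
RF to true tree: 0
```

All 240 locus × taxon haplotypes are recovered by a consensus with ≥ 99%
identity on its confidently-called (uppercase) sites; the 30 trimmed loci
concatenate into a 20,678-column matrix of which 5,116 sites are
parsimony-informative, and the NJ tree is topologically identical
(Robinson–Foulds distance 0) to the tree the reads were simulated from.

The same pipeline is scriptable from the shell:

```bash
ahe sim --seed 11 --out sim/          # FASTQ + truth tables + tree
ahe merge --r1 sim/T01_R1.fastq --r2 sim/T01_R2.fastq --out merged/
ahe run --seed 11 --out run/          # full pipeline, prints a summary
```

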