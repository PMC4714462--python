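# ervkit

An endogenous retrovirus (ERV) analysis toolkit for the desk-scale
computational work behind ERV characterization studies: finding ERV-K-like
proviral insertions in a host genome, deciding whether their reading frames
can still code for full-length proteins, reconstructing spliced *env* mRNAs,
annotating canonical Env structural features with hydropathy profiling,
placing sequences on a bootstrapped phylogram, and the peptide-level
analytics (overlapping peptide libraries, cross-reactivity identity scans,
ELISPOT/ELISA quantification) used to interpret antigen-specific immune data.

It is aimed at virologists and immunogenomicists who want each of these
steps as a tested, scriptable library call rather than a chain of GUI tools,
and it ships a synthetic-data module that generates host genomes with
planted, ground-truth-annotated proviruses so every stage can be validated
without any external downloads.

## What it computes

**Locus discovery** (`ervkit.discovery`). Classic seed-and-extend homology
search: a 2-bit *k*-mer index of the genome (k = 12), ungapped X-drop
extension of diagonal-merged seeds into HSPs (match +1, mismatch −2, X-drop
20), optimal colinear chaining by dynamic programming, and locus calls from
chains covering ≥ 50 % of the consensus. Per-ORF nucleotide identity is
computed from a global affine-gap alignment of each consensus ORF to its
projected locus region,

&nbsp;&nbsp;&nbsp;&nbsp;identity = matched columns / aligned columns,

with gap columns in the denominator, reported to 0.1 %. Flanking LTR pairs
are detected by local self-alignment of the two locus ends.

**Coding potential** (`ervkit.orfs`). Each ORF is classified *intact*,
*frameshift*, *premature_stop*, *truncated* or *not_assessable*. A
frameshift is any indel with length ≢ 0 (mod 3) that disrupts the net
reading frame; a stop codon before 95 % of the consensus ORF length is
premature; compensating indel pairs are reported as defects but the verdict
is made on the translated product. Splice junctions of a captured mRNA are
reconstructed by anchor chaining against the provirus, sliding each junction
within its alignment-ambiguous range to a GT…AG intron (non-canonical
junctions are flagged, not discarded).

**Env features** (`ervkit.envfeatures`). Kyte–Doolittle sliding-window
hydropathy (window 9 for plots, 19 for anchor detection); R-X-(K/R)-R
furin-type cleavage motifs splitting SU from TM; heuristic detectors for the
signal leader (N-terminal hydrophobic core), fusion peptide (hydrophobic
stretch just after cleavage), immunosuppressive (ISU) domain (best ungapped
window against a configurable consensus) and transmembrane anchor
(maximal-scoring window-19 segment with mean hydropathy ≥ 1.6).

**Phylogenetics** (`ervkit.phylo`). p, JC69 and K2P distances with pairwise
deletion; neighbor joining (exact on additive matrices, deterministic
tie-breaks); bootstrap support as the percentage of column-resampled
replicate trees (default 1000) containing each internal bipartition;
outgroup rooting by subdividing the edge separating the outgroup clade.
The engine is distance-based by design; a relaxed-PHYLIP export hook is
provided for external ML re-optimization.

**Immune targets** (`ervkit.peptides`). 15-mer/11-overlap peptide libraries
(C-terminal anchored final peptide; count = ⌈(L−15)/4⌉+1), ungapped
sliding-window identity of an epitope against another proteome (the
cross-reactivity question), ELISPOT quantification (corrected =
mean(stim) − mean(background), floored at 0; SFC per 10⁶ =
corrected × 10⁶ / cells per well) and ELISA quantification
(duplicate-averaged, background-subtracted, not floored), plus a
configurable positivity rule.

## Worked example

```python
from ervkit import simulate, discovery, orfs

# an ancestral provirus (LTR-gag-pro-pol-env-LTR) and a decayed copy with a
# forced 1-nt frameshift in pro; plant both in a 200 kb host genome
pv = simulate.make_ancestral_provirus(seed=8)
spec = simulate.DegradationSpec(
    substitution_rate=0.02,
    forced_defects=[("pro", "frameshift", pv.orfs["pro"][0] + 60)],
    seed=13,
)
decayed, log = simulate.degrade(pv, spec)
genome, truth = simulate.plant(
    200_000, [decayed, pv.sequence], [50_000, 120_000], ["+", "-"], seed=10
)

consensus = discovery.ConsensusModel(pv.name, pv.sequence, pv.orfs, ltr=pv.ltr5)
loci = sorted(discovery.scan_genome(genome, consensus), key=lambda l: l.interval)
for locus in loci:
    ids = ", ".join(f"{o}={v:.1f}%" for o, v in locus.per_orf_identity.items())
    print(f"{locus.chromosome}:{locus.interval[0]}-{locus.interval[1]} ({locus.strand})  {ids}")

local = discovery.locus_local_sequence(loci[0], genome)
for orf in ("gag", "pro", "pol", "env"):
    report = orfs.classify_orf(orfs.align_orf(consensus, orf, local))
    print(orf, "->", report.status)
```

prints

```
chr1:50000-53678 (+)  gag=97.3%, pro=97.3%, pol=98.1%, env=98.5%
chr1:123679-127358 (-)  gag=100.0%, pro=100.0%, pol=100.0%, env=100.0%
gag -> intact
pro -> frameshift
pol -> intact
env -> intact
```

Both planted copies are recovered at their exact coordinates with the
correct strands; the decayed copy shows ~97–98 % per-ORF identity (2 %
substitution decay), and the forced *pro* frameshift is the only defective
reading frame.

The same stages are available from the shell:

```
ervkit simulate --host-length 100000 --n-loci 3 --seed 5 --out sim/
ervkit scan --genome sim/genome.fa --consensus sim/consensus.fa \
            --orfs sim/consensus_orfs.tsv --out loci.gff3
ervkit orfs --genome sim/genome.fa --consensus sim/consensus.fa \
            --orf-table sim/consensus_orfs.tsv --loci loci.gff3 --out orfs.tsv
ervkit splice --transcript sim/transcripts.fa --provirus sim/consensus.fa \
              --out splice.gff3 --protein-out env.faa
ervkit annotate-env --protein env.faa --out env_features.tsv
ervkit phylo --aln aln.fa --model k2p --boot 1000 --seed 7 --outgroup OLD1,OLD2 --out tree.nwk
```

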