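# Methods

This note records the models, conventions and design choices behind
`ervkit`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, what the synthetic data does and does not emulate, and
where the genuinely open design decisions were made.

Coordinates are 1-based and fully inclusive everywhere in the public API
(the convention in which an Env 526–540 peptide spans 15 residues);
conversions to 0-based formats happen only at file boundaries.

## Synthetic data (`ervkit.simulate`)

The generator exists so that every downstream stage can be validated against
known truth. Its components:

* **Ancestral provirus.** Canonical LTR–gag–pro–pol–env–LTR layout with
  byte-identical LTRs (450 nt default), a splice donor in the 5′ leader and
  an acceptor a few bases upstream of *env*, so the spliced subgenomic
  transcript is exon1 (R/U5 leader) + exon2 (*env* through the 3′ LTR). ORFs
  are random non-stop codons between an ATG and a stop; default lengths
  (gag 600, pro 300, pol 900, env 600 nt) keep every alignment in the suite
  comfortably fast while preserving the multi-kb scale of a provirus. The
  LTR tail carries stop codons in all three frames and the bases flanking
  the splice sites are fixed ATG-free context, so the longest ORF on a
  spliced transcript is exactly the *env* CDS — without this, a random
  upstream in-frame ATG would occasionally extend the predicted product.
* **Degradation.** Independent per-site substitutions plus per-site indels
  with geometric(p = 0.5) lengths capped at 10 nt. Forced defects guarantee
  a classifiable lesion: a frameshift is a 1-nt deletion (the smallest
  defect the classifier must detect) and a premature stop substitutes the
  containing in-frame codon to TAA. Every event is logged in ancestor
  coordinates and `apply_mutation_log` is the defining semantics: replaying
  the log must reproduce the degraded sequence byte-for-byte (tested).
  Random events are excluded from forced-defect positions so the planted
  truth cannot be silently reverted.
  A substitution rate of 0.11 reproduces the ~89 % nucleotide identity
  regime of an old, decayed provirus and is the default study condition for
  the scan benchmarks.
* **Planting.** Host chromosomes are i.i.d. DNA with configurable GC. There
  is no repeat landscape, no target-site duplication and no selection model:
  the background exists to measure planted-truth recovery, not to emulate
  repeat-rich genomes, so a perfect score here does not promise
  specificity against real repeat families.
* **Tree evolution.** Jukes–Cantor: along a branch of length *t*
  (substitutions/site) each site differs from its parent with probability
  (3/4)(1 − e^(−4t/3)), uniformly over the three other bases. No indels, no
  rate heterogeneity.
* **Plates.** Well value = background + effect + N(0, σ), floored at zero;
  ELISPOT values rounded to whole spots. Defaults (background 5 spots,
  σ = 2, duplicates, 2×10⁵ cells/well) mimic a quiet IFN-γ ELISPOT.
  Gaussian noise was chosen over Poisson so that σ = 0 gives exactly equal
  replicates (a useful degenerate case in tests); for the estimator-bias and
  false-positive analyses only the first two moments matter.

## Locus discovery

Seed-and-extend with an explicit, fully configurable scoring scheme
(match +1, mismatch −2, gap open −5, gap extend −2, k = 12, X-drop 20,
minimum HSP score 25). Extension is ungapped — indels move the alignment to
a new diagonal, which the chaining stage stitches back together; chaining is
exact dynamic programming over colinear HSPs with query/target gaps ≤ 500 nt
(verified against exhaustive subset search at small n). A chain becomes a
locus when it covers ≥ 50 % of the consensus; same-strand overlapping loci
merge, opposite-strand overlaps do not (nested insertions are real).
Reverse-strand hits are found by scanning the reverse-complemented consensus
against the forward index, which makes strand symmetry exact (tested: scanning
the reverse-complemented genome swaps strands and preserves identities).

Per-ORF identity projects the consensus ORF through the chain's HSP anchors
(linear interpolation between anchors, ±5 nt pad), then globally aligns with
free end gaps on the locus side and scores matched columns over all columns
spanned by the consensus ORF, gaps included. This denominator convention is
a choice — "percent homology" has no single standard definition — and it is
the one anchored by the identity arithmetic test (exactly 11 substitutions
in a gapless 100-nt ORF ⇒ 89.0 %). An ORF with < 50 % chain coverage is
*not assessable*, never 0 %.

LTR pairs: local self-alignment of the two terminal windows (800 nt) of the
locus; a pair is reported when the aligned repeat is ≥ 100 nt at ≥ 80 %
identity. With each LTR decaying independently at rate r, the expected pair
identity is ≈ (1−r)², which the Monte-Carlo test confirms at r = 0.05.

k is accepted in [4, 32] (the 2-bit code fits a uint64); values below ~10
are only sensible for toy inputs. A minimal homopolymer filter stands in
for low-complexity masking and is off by default — synthetic backgrounds do
not need it.

## Coding potential

The classifier answers the biological question — can this frame still make a
full-length protein? — rather than merely counting lesions:

* frameshift: some indel of length ≢ 0 (mod 3) leaves the net frame
  disrupted (cumulative (insertions − deletions) mod 3 ≠ 0);
* premature stop: translating the locus region in the consensus frame hits
  a stop before 95 % of the consensus ORF length. The 95 % threshold
  (configurable) separates decay from natural stop-position jitter;
* compensating indel pairs (net frame 0) are listed as defects but do not
  force frameshift status — the translated product decides;
* a missing ATG or missing terminal stop is *truncated*.

When both a frameshift and a downstream stop are present the status is
*frameshift* and the stop is recorded as an additional defect — the natural
reading of "frameshifts leading to premature stops". An exhaustive
single-substitution scan of a 99-nt toy ORF agrees with a direct
translate-and-check oracle at every position.

Splice reconstruction anchors exact 16-mers, chains them colinearly
(overlaps from junction-straddling ambiguity are trimmed in the chain
score), merges blocks separated by < 50 nt on the provirus (mismatch
patches), and treats larger gaps as introns. Junction placement slides
within the alignment-ambiguous window, nearest-first from the anchored
position, to a GT…AG intron; failing that the anchored position is kept and
flagged non-canonical. Transcripts whose anchored coverage is below 90 %
are rejected as not originating from the locus. Because no real splice
coordinates for the target loci are published, junction accuracy is
validated on synthetic round-trips only (simulation → reconstruction is
exact in the closure tests). CDS selection on a spliced transcript: longest
ATG-initiated ORF, ties toward the 5′ end.

## Env annotation

All detectors are deliberately simple hydropathy heuristics, not trained
predictors; their accuracy is demonstrated on constructed truths, and that
is the claim — no more. Defaults: Kyte–Doolittle scale; window 9 for the
profile, 19 with threshold 1.6 for the membrane anchor (standard practice
values; nothing in the annotated figures fixes a scale or window). The
leader is the first N-terminal run of ≥ 7 residues with per-residue
hydropathy ≥ 1.5 within the first 45 residues, plus a 5-residue C-region.
The fusion peptide is the first ≥ 12-residue window with mean hydropathy
≥ 1.0 starting within 12 residues after cleavage, extended while the mean
stays above threshold. The ISU consensus is a configuration input (the
immunosuppressive domain is conserved in position, not in one fixed
sequence); the CKS-17-like `LQNRRGLDLLFLKEGGL` used in the tests is labelled
synthetic test material, not a biological reference. Among multiple
R-X-(K/R)-R motifs the annotator selects the one whose downstream fusion
window is most hydrophobic — the one yielding a consistent layout — and the
composed annotation always satisfies the ordering invariants (leader from
position 1, SU ends at cleavage, TM starts after it, fusion then ISU then
anchor inside TM), fuzz-tested on 10 000 random proteins.

## Phylogenetics

The tree engine is distance-based: p, JC69 and K2P distances under pairwise
deletion (saturated pairs — arguments of the log ≤ 0 — are flagged and set
to ∞), Saitou–Nei neighbor joining with the Studier–Keppler Q criterion,
Q-ties broken by the lexicographically smallest cluster labels so results
are order-independent, and negative branch-length estimates clamped to 0.
NJ is exact on additive matrices (tested against an exhaustive least-squares
search over all 105 six-taxon topologies, and cross-checked against
scikit-bio's NJ on random matrices). Bootstrap support resamples alignment
columns with replacement — 1000 replicates by default, matching common
practice for published phylograms — and reports the percentage of replicate
trees containing each internal bipartition of the full-data tree;
"high support" flags edges strictly above 95 %. Outgroup rooting subdivides
the edge separating the (required monophyletic) outgroup and preserves edge
supports through the re-rooting.

This replaces a maximum-likelihood search on purpose: the package implements
its methods rather than wrapping an external optimizer, and NJ on these
desk-scale alignments carries the same bootstrap/rooting/support machinery.
The relaxed-PHYLIP export exists for anyone who wants to re-optimize a tree
under ML externally.

## Immune-target analytics

Peptide libraries use the standard epitope-mapping design (15-mers, 11
overlap, step 4) with the final peptide anchored at the C-terminus — the
common vendor convention — giving count = ⌈(L−15)/4⌉+1 and full coverage.
Cross-reactivity scans are ungapped by construction: the question is whether
any contiguous peptide of the target could be confused with the epitope, so
identity is exact positional matches over epitope length at every window,
with display percentages rounded half-up.

ELISPOT: corrected spots = mean(stimulated) − mean(background), floored at
zero (a negative spot count is noise), SFC per million from cells per well;
an optional summed-duplicates mode reproduces the summed-response reporting
convention. ELISA: duplicate-averaged, background-subtracted, *not* floored
(peptide-array plots conventionally show negative baselines). Both are
linear in the well values. The default positivity rule — corrected ≥ 10
and stimulated mean ≥ 2× background mean — is calibration-driven, chosen so
the false-positive rate on null plates under the default noise model stays
below 5 %; no published threshold exists for these assays, and the rule is
recorded in every output.

## Problem sizes

The validation suite runs at the scale the analyses describe: a 5 Mb
three-chromosome genome with three planted insertions for the scan
benchmark; 50 replicates for splice closure, Env constructed truths and NJ
additive matrices; 200 randomized ORF-status calls; 1000 bootstrap
replicates; 1000 simulated plates and 1000 random library lengths. These
sizes keep the full suite and the acceptance script each under a minute on
one CPU.

## Known limitations

* The scan is tuned for planted-truth recovery on desk-scale genomes; it is
  not engineered for whole-genome repeat annotation, repeat-family
  clustering or solo-LTR discovery.
* Leader/fusion/anchor detection are heuristics with no claim of accuracy
  on real signal peptides beyond the constructed-truth regime; glycosylation
  sites and 3-D structure are out of scope.
* The splice mapper handles single transcripts against single loci with
  near-exact homology, not spliced alignment at scale, readthrough, or
  non-standard codes.
* The degradation model is a stand-in for whatever decay process actually
  shaped a given locus; it is a test substrate, not an inference target.
* Distance/NJ trees are not ML trees; for publication-grade phylogenies the
  PHYLIP export and an external optimizer are the intended route.
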