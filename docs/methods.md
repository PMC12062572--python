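# Methods

svscout calls germline structural variants (SVs) — deletions (DEL),
insertions (INS), tandem duplications (DUP), inversions (INV) and
translocations (TRA) of 50 bp and above — from long-read alignments.
The pipeline has three stages: (1) a learned screen that flags 200 bp
blocks of the genome whose alignment features look variant-like,
(2) read-level signature extraction and mean-shift breakpoint
clustering inside the flagged regions, and (3) a coverage-adaptive
support filter plus an ensemble genotyper that emit the final VCF.
A built-in simulator generates every dataset the tests and the
acceptance script use.

## Alignment feature matrices

For every reference site in a scanned region the `features` module
counts ten evidence channels separately per strand (20 channels total):
read depth; deletion coverage (reference positions under a CIGAR `D`
operation of at least `min_op` = 30 bp); insertion anchors (`I` >= 30 bp);
left and right soft-clip counts; four split-read channels derived from
the SA tag of the primary alignment (same-strand distant split,
opposite-strand split, overlapping/backward split indicating a tandem
duplication, and inter-contig split); and low-identity coverage, the
span of reads whose NM-derived edit fraction exceeds twice the regional
mean. Reads under mapping quality 20 and secondary alignments are
ignored; supplementary records are skipped because their junctions are
already represented by the primary's SA tag, which also guarantees each
junction is counted once per read. The 30 bp `min_op` floor is
deliberately below the 50 bp reporting threshold: sequencing error
fragments long events into shorter CIGAR operations, and the deficit is
recovered when cluster median lengths are computed.

The channel set is one deliberate open choice of this implementation —
it is isolated behind a single constructor so an alternative definition
can be swapped in without touching the model.

Matrices are tiled into 2000 bp windows of ten 200 bp submatrices; a
trailing partial window is zero-padded and the fully empty submatrices
are masked.

## Window classification model

Each 200 bp x 20 submatrix is `log1p`-transformed and encoded by two
same-padded 1-D convolutions over the position axis (kernel 5, channels
16 then 32) followed by channel attention (squeeze-excite over pooled
positions, reduction ratio 8) and spatial attention (a kernel-7
convolution over channel-pooled summaries), then mean-pooled and
projected to a 64-dimensional embedding. The ten embeddings of a window
receive a sinusoidal positional encoding and pass through two pre-norm
transformer layers (4 heads, feed-forward 128) before a shared linear
head scores each submatrix; padded submatrices are excluded from
attention and forced to probability zero. Submatrices at or above the
positive threshold (0.5) become candidate intervals, and adjacent
positives merge into candidate regions by taking the minimum of starts
and maximum of ends.

Numerical choices that mattered in practice, all visible in
`ModelConfig`:

* **Pre-norm residual blocks with zero-initialised output projections.**
  The attention and feed-forward branches start at identity, so the full
  model begins exactly as the CNN encoder plus head and learns the
  cross-submatrix refinement on top. Post-norm blocks trained unstably
  at this scale.
* **Input LayerNorm before positional encoding.** Raw encoder
  embeddings are roughly ten times smaller than the sinusoidal encoding;
  without normalisation the early layers see mostly position and
  training stalls.
* **Class weighting.** Binary cross-entropy with the positive class
  weighted by the negative/positive label ratio of the training set
  (SV-overlapping submatrices are rare).
* **Optimisation.** Adam at 1e-3, batches of 32 windows, up to 20
  epochs with early stopping (patience 5 on validation loss); the
  best-validation-loss parameters are returned. Dropout defaults to 0 —
  at a few hundred training windows it only added variance.
* One integer seed drives parameter initialisation, data shuffling and
  the simulator labels. Training runs in minutes on one CPU; the whole
  model is a few hundred thousand float32 parameters on a small
  numpy-based autodiff core (`nn.py`).

Three variants exist for the ablation harness: `full`, `cnn_only` (no
transformer; each submatrix scored from its own embedding) and
`transformer_only` (a linear patch embedding replaces the convolutional
encoder).

## Signatures and clustering

Within each candidate region (extended by 1 kb) the alignments are
re-scanned. Intra-alignment evidence: every CIGAR `D`/`I` operation of
at least 30 bp becomes a DEL/INS signature at its reference position.
Split-read evidence: the primary alignment plus its SA-tag segments are
ordered by read coordinate and each adjacent pair is classified —
different contigs give a breakend (BND) pair, opposite strands an INV
spanning the two junctions, same-strand backward reference order a DUP
of the overlapped span, and otherwise a reference gap >= 30 bp is a DEL
and an unaligned read gap >= 30 bp an INS. Up to 100 bp of
read-coordinate slack is ignored at junctions (alignment-boundary
jitter). The same junction observed from both sides of a breakend is
deduplicated per read.

Signatures of one type on one contig are clustered by mean shift on the
breakpoint coordinate under a Gaussian kernel. Bandwidths follow the
per-type policy — 1000 bp for DEL, 300 for INS, 500 for DUP and INV —
and widen to 1500 bp when the sample's mean read error rate is below
0.10, on the grounds that low-error alignments scatter less and a wider
kernel can then pool a broader neighbourhood. Whether the widened
bandwidth should apply to all types or only some is an open point; it
applies to all four here and is isolated in `select_bandwidth`. Each
point ascends the kernel density estimate until its shift falls below
0.01 bp (up to 2000 iterations — a coarser tolerance stalls trajectories
on shallow density shoulders); converged modes closer than half a
bandwidth merge, ties resolving toward the smaller coordinate. Clusters
are then refined by length: members sorted ascending, a new subcluster
opening whenever the next length differs from the open subcluster's
first member by at least the cluster median length times 0.7. The
comparison against the first (shortest) member makes the rule
deterministic. Breakends are not density-clustered: two BNDs join a
cluster when they connect the same contig pair with both ends within
1000 bp, and the cluster's breakpoints are the per-end medians.

## Support filtering and genotyping

A subcluster becomes a call if its distinct supporting reads reach

    min_support = ceil( mu * C_global^phi * (1 + rho * tanh((C_local - C_global) / C_global)) )

with C_global the genome-wide mean depth and C_local the depth within
500 bp of the locus. Defaults mu = 1.0, phi = 0.6, rho = 0.4, floor 2;
when the read error rate reaches 0.10 or C_global falls below 10 the
softer set mu = 0.8, rho = 0.3 is substituted so sparse but genuine
signals at low coverage survive. These constants put thresholds in the
2–10 read range conventional for 5–70x long-read calling (ceil(30^0.6)
= 8 at 30x) and are all exposed in `SupportModelParams`.

Genotypes come from a vote of three methods applied to the counts of
variant-supporting reads versus reference-spanning reads (reads fully
covering the locus ± 50 bp without a matching signature), with the
locus error rate epsilon clamped to [0.02, 0.45]: (1) Bayesian
posterior over binomial likelihoods (alt-read probability epsilon, 1/2,
1 − epsilon for 0/0, 0/1, 1/1) with default priors (0.4, 0.4, 0.2);
(2) EM reweighting of the three-genotype mixture started from uniform
weights (tolerance 1e-6, 100 iterations) — for a single locus this
converges to the maximum-likelihood genotype, providing a prior-free
vote; (3) the support-ratio rule (ref fraction > 0.7 gives 0/0, alt
fraction > 0.7 gives 1/1, otherwise 0/1). Majority wins; a three-way
tie falls to the Bayesian result because it integrates the prior and is
deterministic. The pure-likelihood argmax is logged per call as a
diagnostic. Loci with no informative reads are emitted as `./.`.

Calls PASS when support meets the threshold and (for intra-contig
types) the median length reaches 50 bp; failed records are retained
with `MinSupport` / `MinLength` filter labels. VCF 4.2 output uses
symbolic ALTs, SVLEN negative for deletions, END = POS + |SVLEN|, and
translocations as two mated bracket-notation BND records.

## Simulator

The simulator emulates a variant-implanted donor genome sequenced with
error-prone long reads, in the style of benchmark sets built by
implanting SVs into a reference and simulating reads from the donor.
Default conditions: two 1 Mb uniform-random contigs; 20 SVs per type
sized 60–2000 bp placed with at least twice the maximum size between
events and 10 kb from contig edges; heterozygous fraction 0.5 (each het
event lands on one random haplotype); 30x coverage of 8 kb ± 1.5 kb
reads; 10% error. Translocations are reciprocal exchanges between the
two contigs with breakpoints paired in sorted order, so each haplotype's
derivative chromosomes alternate cleanly and every reference base keeps
single-copy coverage.

Alignments are constructed analytically from the truth rather than by
running an aligner: a read crossing a deletion receives a `D` operation
at the exact truth offset, an insertion an `I` operation, and
inversion/duplication/translocation junctions become split alignment
records with SA tags, correct strands and soft clips. Sequencing noise
is substitutions (60% of the error budget) and 1–3 bp indels (40%),
reflected consistently in CIGAR, sequence and NM; small indels never
approach the 30 bp signature floor, so noise cannot mimic an SV. Split
segments shorter than 100 bp are left soft-clipped, as an aligner would.
Every byte of the sorted BAM is a deterministic function of the seed.

What the simulator does **not** emulate — and therefore what passing
tests do not establish about real data — includes platform-specific
error profiles (homopolymer bias, chimeric reads), alignment ambiguity
in repeats (the reference is uniform-random, so mapping is essentially
unambiguous and mapping quality is constant), SVs near assembly gaps,
nested or overlapping events, and somatic mosaicism. Results on the
simulator are an internal-consistency check of the pipeline, not a
benchmark claim about real genomes.

## Training protocol and evaluation

The standard model trains on two simulations (2 x 300 kb contigs, six
SVs per type, sizes 60–1000 bp) at 30x and 10x coverage so the
classifier sees depth variation; labels mark every 200 bp submatrix
overlapping a truth interval (insertions and breakends count as 1 bp
anchors). Training seeds are offset from the user seed and independent
of the benchmark simulation's seed.

Benchmark evaluation matches calls to truth one-to-one and greedily by
position: same type, breakpoint within 500 bp (inclusive), and the
shorter length at least 0.7 of the longer; breakends instead require
both ends within tolerance and skip the length test. Precision, recall,
F1 and breakpoint-offset statistics are reported per type and overall.

The ablation harness trains `full`, `cnn_only` and `transformer_only`
on the same split under the same 20-epoch budget with early stopping
and compares them on a held-out simulation. Its headline metric is
window-level F1 (a 2 kb window is positive when any live submatrix is):
the window is the decision unit feeding region merging, whereas
submatrix-level F1 — also computed and reported — penalises the
harmless spill-over of positive probability into blocks bordering a
variant. Problem sizes throughout (300 kb training contigs, 1 Mb
benchmark contigs, 200 oracle instances, 3000 genotyper loci) were
chosen so the whole cycle runs comfortably on a single CPU.

## Known limitations

* The ten-channel feature definition is this package's own; it covers
  the five signature classes but is not a tuned or published set.
* Nested, overlapping and somatic SVs are out of scope; one signature
  per (read, type) is counted per cluster, so multi-junction complex
  events collapse.
* Genotyping treats reads as independent Bernoulli draws; mapping bias
  and multi-allelic sites are not modelled.
* The mean-shift implementation is O(n^2) per region and type — fine
  for per-region signature counts, not for genome-wide unscreened
  input.
* At 5x coverage heterozygous events sit near the support floor; recall
  degrades by design rather than precision.
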