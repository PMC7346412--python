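# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `pseudoplast`. It is written for a reader who wants to
know exactly what each number produced by the package means.

## Coordinate model and I/O

Plastome records are circular; internally all feature coordinates are
0-based half-open on the forward strand. A gene segment may wrap the origin
(`end <= start` means `[start, L) + [0, end)`); the sequence is never
doubled. GenBank's 1-based inclusive `join`/`complement` locations are
converted on read and reconstructed on write, so a read→write→read round
trip is the identity on sequence, segments, strands and feature kinds.
Translation uses the bacterial/plastid genetic code (NCBI table 11,
configurable); codons containing ambiguity codes translate to `X`, which is
excluded from hydrophobicity denominators.

## Inverted-repeat detection

The IR finder seeds on maximal exact matches between the genome and its
reverse complement (k-mer anchoring, k = min(min_len, 21), deduplicated per
diagonal), keeps pairs of disjoint segments at least `min_len` (default
1,000 bp) long, and extends each pair outward under a mismatch tolerance.
Extension bookkeeping is chunk-local: a pending run of mismatches plus
following matches is accepted only if the *chunk's own* mismatch fraction is
within `max_mismatch_frac` (default 0.01) and it ends on a match. This lets
the extension bridge isolated substitutions between slightly diverged IR
copies but prevents a long exact seed from bankrolling absorption of random
flanking sequence; the cost is that a mismatch closer than ~1/frac bases to
the true boundary leaves the boundary conservatively short. Ties in repeat
length raise a diagnostic rather than guessing; the longest single-copy gap
is labelled LSC, and IRb is the copy adjacent to the LSC's downstream end.
Detection does not extend across the origin; inputs are expected to begin in
a single-copy region, the near-universal convention for deposited plastomes.

The partition identity `lsc + ssc + 2*ir == genome length` is asserted
whenever a structure is found. SSC orientation is standardized by
reverse-complementing the SSC in place when the anchor gene (default
`ndhF`) lies on the minus strand; the operation is idempotent and remaps
only features fully inside the SSC.

## Annotation lift

Gene models are lifted from an annotated reference by exact k-mer seeding of
the strand-corrected CDS against the target (both orientations, offset
voting), followed by affine-gap alignment of the CDS to the candidate
window with free end gaps. A model transfers when identity over the
reference length is at least `min_identity_for_lift` (default 0.70, the
conventional cutoff for plastome annotation transfer); otherwise the gene
is recorded as missing, never raised. Lifted models are single-segment;
intron-containing genes would lift as their dominant exon block, a known
limitation irrelevant to the intron-free synthetic panels.

## Pseudogene criteria

Each focal gene region (annotated span plus a 200 bp downstream margin for
termination scanning) is globally aligned to the reference CDS with affine
gaps (match +2, mismatch −3, open −10, extend −0.5; the aligner's first
optimal alignment is taken, which is deterministic). Events:

- **frameshift** — the first gap run after which the cumulative
  (insertions − deletions) balance is not ≡ 0 mod 3; compensated indel
  pairs are therefore still flagged at the first offending indel.
- **premature_stop** — an in-frame stop of the focal reading frame (the
  frame of the focal sequence itself, anchored at its start; for partial
  contigs, anchored to the reference frame at the first aligned column)
  strictly upstream of the reference stop column.
- **lost_canonical_stop** — no focal in-frame stop at or within 30 bp
  downstream of the reference stop column; if the nearest downstream stop
  lies beyond that window, a **novel_termination** event records the
  extension length.
- **large_deletion** — any single focal gap run ≥ 100 bp (per gap, not
  cumulative; threshold configurable).
- **short_inversion** — the aligner renders an in-place inversion as a
  mosaic of mismatches and compensating indels, so the detector segments
  the alignment into "noisy blocks" (runs of non-identical columns
  separated by < 15 clean matches), requires near-equal sequence content on
  both rows, and calls an inversion when the reverse-complemented focal
  segment beats the direct comparison by ≥ 0.25 identity, where both
  identities are best-shift ungapped identities (shifts up to ±100,
  overlap ≥ max(20, m/3)) so the comparison is like-for-like. Gap runs
  inside a called block still count toward the frame balance but are not
  double-reported as deletions.
- **length_anomaly / hydrophobicity_outlier** — supporting evidence from
  the panel: predicted protein length outside the panel orthologs' range,
  or hydrophobic fraction outside the Student-t confidence interval of the
  panel mean (level 0.95). "Hydrophobic" defaults to the positive
  Kyte–Doolittle hydropathy set {A, C, F, I, L, M, V}; the set is
  configurable because usage varies across the literature.

A gene is called a **pseudogene** only on a primary structural event
(premature stop, frameshift, lost canonical stop, large deletion — a short
inversion makes the call through the stop it creates); supporting evidence
alone yields **anomalous**. Genes conventionally fragmented by IR
boundaries (`ycf1`, `ycf2`, `ycf15`) are excluded from novel calls by
default. The 95 % interval is a t-based CI of the panel *mean*; with
realistic panels it is much narrower than the panel range, so
hydrophobicity outliers are common and deliberately non-primary.

## Codon model and selection test

Likelihoods use a GY94-style model on the 61 sense codons. Off-diagonal
rates are zero for multi-nucleotide changes and proportional to κπ_j
(synonymous transition), π_j (synonymous transversion), ωκπ_j and ωπ_j
(nonsynonymous), with rows normalized so that one unit of branch length is
one expected substitution per codon under that branch's ω. π is F3x4 from
the alignment's position-specific nucleotide frequencies (0.1 pseudocount
per nucleotide; stop-codon mass redistributed proportionally; frequencies
floored at 1e-10). Transition matrices come from the symmetrized
eigendecomposition (the chain is reversible), cached per (κ, ω).

Pruning runs over site patterns with per-node rescaling. Internal stops,
gaps and ambiguous codons are missing data (a tip vector of ones). Branch
parameters are keyed by canonical bipartition (the side of the split not
containing the lexicographically smallest taxon), which is stable under
rerooting; a bifurcating root's two edges share one key and act as a single
merged branch, so likelihoods are invariant to root placement — asserted
numerically, not just by construction, in the tests.

The **full** model is free-ratio (one ω per branch); the **constrained**
model equates the focal terminal branch's ω with its immediately ancestral
branch's (df = 1). Both estimate κ and all branch lengths; bounds are
ω ∈ [1e-6, 999], κ ∈ [1e-3, 100], t ∈ [1e-8, 50]; optimization is L-BFGS-B
on log-parameters, multi-start (3 seeded starts by default). `fit_lrt_pair`
is the recommended entry point: it warm-starts the full model from the
constrained optimum (the full model contains the constrained one, so
Λ ≥ 0 structurally) and then refits the constrained model from the full
optimum's projection, keeping the better constrained fit — optimizer
hygiene that stops an under-converged null fit from inflating Λ. Λ is
referred to χ²₁; Hochberg's step-up rule adjusts across genes.

Pseudogene sequences need preprocessing before codon-model fitting, since
the model assumes in-frame, same-strand sequence: internal stops are
recoded as missing by `build_codon_alignment`; the pipeline additionally
truncates a focal copy at its first uncompensated frameshift (the
downstream tail no longer codes in the reference frame and would masquerade
as a burst of nonsynonymous change) and recodes detected inversion spans to
N. This is the codon-aware analogue of removing ambiguously aligned
regions. Sequences with fewer than 200 unmasked bp are dropped from gene
matrices; alignments with fewer than three surviving taxa are rejected.

## Synthetic study conditions

The generator's defaults define the conditions every verification runs
under; they are a scaled-down but structurally faithful plastome study:

- panel of 8 taxa on a pectinate tree, branch lengths 0.03
  substitutions/codon, focal tip nested one node deep so an ancestral
  branch exists;
- 19 protein-coding genes of 90–320 codons (real plastomes carry 79+;
  gene count and lengths are scaled for tractability), three tRNAs, two
  rRNAs inside a 4 kb IR; spacers are uniform-random at GC 0.37
  (plastome-like), regenerated per genome; focal spacers scaled by 0.8,
  emulating the intergenic erosion that makes degraded plastomes the
  shortest in their clade;
- codon evolution by exact stochastic simulation (jump chain) under the
  same rate matrices the likelihood code builds, background ω = 0.2, focal
  and ancestral branch ω = 0.03 — the strong-purifying, no-regime-shift
  condition; per-branch synonymous/nonsynonymous event counts are retained
  so simulator and likelihood can be cross-checked (mean substitutions per
  codon per branch equal the branch length within Monte-Carlo error);
- all randomness flows from one seed through labelled child streams
  (`SeedSequence` spawn keys), so adding a gene or taxon does not perturb
  other draws, and equal seeds give byte-identical output;
- the injected lesion set mirrors a degraded semi-aquatic plastome: four
  frameshifted genes, a point-mutation stop, an inversion-created stop, and
  a gene with a large in-frame deletion plus a shifted termination
  (no stops). Frameshifts are placed in the 3′ third of each gene so the
  in-frame portion passes the ≥ 200 bp rule; termination-shift extensions
  are floored to a multiple of 3 because a novel stop must sit on the codon
  grid; the planted IR boundary is guarded against chance single-base
  extension so that construction is a valid oracle for exact recovery.

What the synthetic data do **not** emulate: introns and RNA editing,
sequencing error, heteroplasmy, real intergenic homology (spacers are
independent noise, so annotation lift is easier than on real genomes), and
genome-scale alignment artefacts. Passing tests therefore demonstrate the
correctness of the machinery under the stated model, not robustness to
every artefact of real assemblies.

Mapped-read summaries are simulated at the study's conditions (focal
plastid read fraction 3.4 %, panel mean 10.1 % with SD 2.5) for the
comparative read-fraction test; the genome-size test uses the actual
generated genome lengths.

## Calibration and verification sizes

The test suite and acceptance script verify, at these problem sizes chosen
to keep a full run in single-digit minutes on one core:

- planted-IR recovery: 100 genomes, IR 500–30,000 bp, exact boundaries at
  zero mismatch tolerance;
- lesion round trip: 50 seeded injections per kind — sensitivity 1.0
  required for stops, frameshifts, large deletions and lost stops, ≥ 0.9
  for short inversions (the aligner's rendering of an inversion is not
  always recoverable); zero structural events across all un-mutated panel
  genes;
- likelihood: pruning equals an explicit sum over all internal-node codon
  assignments to 1e-8 on fixtures up to 5 taxa × 6 codons, and is invariant
  to root placement to 1e-8;
- LRT null calibration: 300 replicates at 300 codons on a 4-taxon tree with
  a single deterministic start per fit (a runtime scaling of the 3-start
  default; the refit step above makes additional starts redundant on null
  data) — the rejection rate at α = 0.05 must fall in the exact binomial
  95 % interval. The statistic runs slightly hot at these sizes (χ²₁ is an
  asymptotic reference; rates around 6–8 % occur at some seeds), a known
  finite-sample property of free-ratio LRTs rather than an optimizer
  artefact;
- ω recovery: median ω̂ over 50 replicates at true ω = 0.03, 500 codons,
  must lie in [0.01, 0.09].

## Known limitations

- The IR finder reports the maximal repeat pair; tandem or rearranged
  repeat architectures (rare, clade-specific) raise a tie diagnostic
  instead of a call.
- Frameshift calls follow the any-prefix rule, so a compensated ±1/∓1 indel
  pair is still flagged — intentional for pseudogene screening, but not a
  claim that the downstream protein is out of frame.
- Per-branch ω estimates on short branches are noisy and frequently hit the
  lower bound (ω̂ → 1e-6 prints as 0); medians across replicates are the
  meaningful summary.
- The pipeline's paralog stage synthesizes contigs from the focal copies
  (the assembler boundary is an input in real use); gene-tree inference on
  the prepared matrices is out of scope and left to external tools.
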