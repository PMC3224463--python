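# Methods

## The question and the procedure

The package tests whether 5'UTR length tracks organismal complexity across
species, and probes the mechanisms that could mediate such a link.
Organismal complexity is operationalized as the number of distinct cell
types per species; regulatory complexity is measured from multi-tissue
expression data as (a) the ratio of non-constitutively to constitutively
expressed genes and (b) the τ tissue-specificity index. The translational
side is measured by counting upstream start codons (uAUGs) and upstream
open reading frames (uORFs) in 5'UTRs. Five hypothesized connections are
evaluated: length↔specificity (i), specificity↔complexity (ii),
length↔uAUG/uORF abundance (iii), uAUG/uORF↔complexity (iv), and
length↔complexity (v).

The pipeline runs four stages over per-species inputs:

1. **Catalog.** Transcripts are kept only if they have an annotated 5'UTR,
   `known` status, and a known protein product — conditions under which both
   UTR termini are experimentally supported. One representative per gene is
   chosen either uniformly at random (seeded) or as the isoform with a
   *pure* 5'UTR, i.e. one whose UTR overlaps no coding interval of any other
   transcript on the same chromosome and strand. Optionally, transcripts are
   further required to have their TSS inside a CAGE tag cluster (± a
   configurable slack in bp; exposed rather than fixed because "support"
   could mean containment or proximity). Lengths are summarized as median,
   mean, and median absolute deviation in bp.
2. **Scan.** Each representative 5'UTR is scanned in all three frames. Every
   ATG occurrence counts as a uAUG. A uORF opens at the first ATG of a frame
   not already inside an open uORF, closes at the first in-frame stop
   (TAA/TAG/TGA) lying entirely within the UTR, and is reported only if at
   least 9 nt long (start, stop, ≥1 codon between). In-frame ATGs inside an
   open uORF are suppressed, so no two uORFs of one frame share a stop. An
   ATG with no downstream in-frame stop contributes to the uAUG count but
   yields no uORF. Sequences are treated as DNA (U→T, case-insensitive); any
   triplet containing N is neither start nor stop.
3. **Express.** A gene is called expressed in a tissue if its intensity is
   strictly greater than the cutoff (default 200), or, for per-replicate
   present/absent data, if at least 3 of 4 replicates are present. Because
   tissue panels differ in size between species, k tissues (default 10) are
   resampled without replacement n_reps times (default 1,000); per replicate,
   genes expressed in none of the sampled tissues are dropped, and three
   measurements are taken over the analyzed genes: median 5'UTR length,
   log2(non-constitutive/constitutive), and mean τ computed from the
   sampled-tissue values. τ = Σᵢ(1 − xᵢ/x_max)/(N − 1); negative values are
   clipped to 0 first; an all-zero gene has no τ. A replicate with no
   constitutive gene reports the ratio as missing, never imputed. Replicate
   distributions are compared between species by the Mann–Whitney U test
   (exact for both n ≤ 8, tie-corrected normal approximation otherwise).
4. **Contrast.** Species traits are correlated by Felsenstein's independent
   contrasts: for siblings with values x₁, x₂ and extended branch lengths
   v₁, v₂, the standardized contrast is (x₁−x₂)/√(v₁+v₂), the ancestral
   value is the precision-weighted mean, and the parent branch is inflated
   by v₁v₂/(v₁+v₂). Multifurcations are resolved with zero-length
   bifurcations (logged). Contrast pairs are jointly sign-flipped so the
   x-member is nonnegative and the regression is forced through the origin
   (no change in one trait ⇒ no expected change in the other). Both the
   uncentred R² of the through-origin fit and Spearman's ρ on the
   positivized pairs are reported, alongside the plain Spearman on the raw
   pairs, because "rank correlation of a zero-intercept model" admits either
   reading. The p-value for ρ uses the t-approximation with n−1 degrees of
   freedom (one parameter is spent on the slope); simulation (500 null
   16-tip panels) puts the realized type-I rate at ≈0.05.

## Synthetic panels and what they do (not) emulate

The generator produces everything the pipeline consumes, with planted truth
written to a side directory the analysis never reads; the pipeline always
round-trips through the on-disk formats.

* **Tree**: pure-birth (Yule) with unit birth rate, grown to the requested
  tip count, plus one final exponential hold so the youngest pendant
  branches are strictly positive.
* **Traits**: two traits evolve jointly by Brownian motion with per-branch
  increment covariance ρσ₁σ₂t. Trait 1 is the species' log-median 5'UTR
  length (root 4.8 log-bp ≈ 122 bp, σ = 0.4 per unit branch length — chosen
  so the cross-species spread of log medians matches the roughly 0.4–0.6
  SD seen across real vertebrate/invertebrate catalogs); trait 2 is log
  cell-type count (root log 150, σ = 0.4), exponentiated for the trait
  table.
* **Annotations**: genes carry 1–4 isoforms (45/30/15/10%), mixed statuses
  (85% known), protein-product flags (90%), and UTR presence (90%); UTR
  lengths are lognormal (σ = 0.9 log-bp, matching the ~1.5 mean/median
  ratio of real catalogs), clipped to [10, 4800] bp. Loci are laid out on
  disjoint genomic lanes so planted purity is exact by construction:
  a transcript is non-pure iff a CDS fragment of a sibling isoform was
  injected inside its UTR (30% of multi-isoform UTR-bearing transcripts by
  default). Sequences are i.i.d. nucleotides at 45% GC.
* **Expression**: a fraction of genes (default 0.3) is constitutive —
  near-uniform means of 500–5000, above the intensity cutoff in every
  tissue by construction. The rest distribute a total budget over tissues
  by a symmetric Dirichlet with concentration 1/(1+specificity_strength),
  a single monotone knob for τ. True τ comes from the noiseless means.
  Intensity mode multiplies means by lognormal noise (σ = 0.1); calls mode
  draws 4 Bernoulli replicates per tissue with presence probability
  following a Hill curve (exponent 3) of the mean centred at the cutoff —
  in calls mode the "constitutive everywhere" guarantee is therefore only
  probabilistic.

Not emulated: introns/promoters, sequence evolution along the tree,
homologous-tissue structure, array normalization artifacts, or annotation
error correlated with study intensity. Passing tests therefore demonstrate
correctness of the measurement and inference machinery under the stated
generative model, not robustness to real-data biases.

## Numerical and design choices

* Coordinates are 0-based half-open internally; annotation tables on disk
  are 1-based inclusive (GFF convention), CAGE clusters are BED (0-based).
  Intron-interrupted UTRs may carry several sub-intervals; length is the
  summed width, the TSS the strand-aware outermost base.
* Pure-mode ties are broken by lexicographically smallest transcript id —
  deterministic without a seed. Random-mode selection derives a per-gene
  RNG from (seed, CRC32 of the gene id), so results do not depend on gene
  order.
* The homology-based purge of pure 5'UTRs against an external protein
  database is represented by a boolean `excluded` annotation column,
  honored during pure-mode selection (generator default fraction 0).
* τ is the standard max-normalized form. The intensity cutoff is strict
  (value > 200, not ≥).
* A uORF whose stop falls beyond the UTR end is not counted; uORFs in
  different frames may overlap freely.
* One root seed derives per-stage seeds by XOR with a CRC32 hash of the
  stage name; identical config+seed gives byte-identical reports.
* Problem sizes in the validation suite are scaled down from data-scale
  runs: end-to-end recovery uses 15 species × 2,000 genes (real catalogs
  have 12,000–16,000 analyzed genes per species; 2,000 keeps the median's
  sampling error well below the Brownian signal), resampling checks use
  5,000–15,000 genes, and calibration uses 300–500 simulated trees.

## Known limitations

* The contrast p-value's n−1 df t-approximation is slightly anticonservative
  for very few species; an exact view can be had by comparing the reported
  plain-Spearman p.
* Through-origin R² is not comparable to centred R²; it can exceed the
  squared Pearson correlation.
* With strong specificity and few sampled tissues, many genes are expressed
  nowhere in a sample and are excluded, so replicate summaries can rest on
  few genes; the per-replicate gene counts are reported for that reason.
* The generator's planted purity relies on its disjoint-lane layout; real
  annotations with overlapping gene loci exercise the same interval logic
  but have no ground truth.
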