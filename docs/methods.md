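# Methods

`oryzaloss` implements a comparative end-sequence analysis of gene loss: a
reference genome is compared with sets of BAC end sequences (BESs) sampled
from the genomes of close relatives, and the fraction of relative BESs that
fail to map back to the reference is turned into an estimate of how many
genes the reference lineage has lost.  This note records the models, the
defaults and the numerical choices; nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimators

For each species, let `L` be its genome size in bp (an external input, e.g.
flow cytometry), `r` its non-repetitive fraction, and `m` the fraction of
its BESs that map to the reference.  With `d` the gene density per
non-repetitive site, the estimators are

    n_g = d · L · r                    total genes
    n_u = n_g · h_u / (h_u + h_m)      species-specific (reference-lost) genes
    R_C = L · r · m                    genome length conserved with the reference

`h_u` and `h_m` count unmapped and mapped BESs that carry protein homology.
The `n_u` identity rests on the assumption that within the gene-bearing
fraction, the homology rate of BESs is the same in shared and unique
regions, so the ratio of gene-bearing unmapped to gene-bearing mapped BESs
estimates the ratio of unique to shared genes.

The reference's own density is `d_ref = n_genes_ref / (L_ref · r_ref)`.
Densities of the other species are `d = d_ref · w` with the weight

    w = (N_pc / N_all) / (J_pc / J_all)

where `N_pc` counts the species' BESs whose placement overlaps a reference
protein-coding region by more than 50 bp, `N_all` all of its BESs used for
mapping, and `J_pc / J_all` the same ratio for fragments simulated from the
reference genome itself.  The simulated fragments pass through the same
masking and minimum-unmasked filter as real BESs, so both ratios share a
denominator model; without this the weight is biased upward by the fraction
of repeat-dominated reads.

Two conventions are reported for `n_u`.  The *conservative* estimate counts
ambiguously mapped BESs as mapped (their homology hits join `h_m`), which
can only lower `n_u`; the *liberal* estimate counts them as unmapped.  `m`
in `R_C` uses strictly mapped BESs only — with the published mapping counts
this is the choice that reproduces the printed conserved-region sizes.

A structural property worth knowing: unmapped BESs cannot overlap reference
annotation, so `N_pc/N_all` (and hence `n_g`) is diluted by the unmapped
fraction.  At the few-percent loss levels the method is designed for this
is negligible; it grows linearly with the lost fraction, which is why the
synthetic validation operates in the same few-percent regime.

## Classification and mapping

A BES is **mapped** when some hit reaches identity ≥ 0.80 and query
coverage ≥ 0.70, otherwise **ambiguous** when some hit reaches identity
≥ 0.80 and coverage ≥ 0.30, otherwise **unmapped**.  A hit passing the
identity bar with coverage below 0.30 is unmapped: the unmapped rule
("identity < 80% or coverage < 30%") is the defining one and takes
precedence over a literal reading of the ambiguous rule.  Identity is
matched columns over aligned columns of the best local alignment; coverage
is aligned query bases over full query length (masked bases included in the
denominator).

The aligner is a seed-and-extend local aligner: exact 13-mer seeds (from
unmasked query bases when a mask is present; reference seeds from unmasked
reference positions), diagonal voting in 24-diagonal bins, then an
affine-gap local (Gotoh) dynamic program over a window around each
candidate diagonal, banded to ±48 diagonals around the seed span.  Scoring
is match +1, mismatch −2, gap open −5, gap extend −2 (a gap of length k
costs −5 − 2k).  Within the band the recurrence is exact, so on small
references the best score equals the full Smith–Waterman optimum; the band
exists purely to bound cost on long references.  Over-represented seeds are
subsampled to 256 loci rather than dropped, so reads lying entirely inside
a high-copy repeat still seed somewhere.  Candidates are extended in vote
order with early stopping once a confident hit exists and remaining
candidates have under half its votes; equal-best repeat copies have similar
vote counts, so multi-mapping detection survives the early stop.

Placement dedup before the codon analysis: queries with more than one
equal-best placement (same identity and coverage) are discarded; when
several queries occupy the same reference position the highest identity
wins, ties broken by query id.

## Repeat masking

K-mer mode counts canonical k-mer multiplicities on the reference and masks
every base covered by a k-mer whose multiplicity reaches the threshold;
library mode takes a repeat FASTA or BED.  Defaults are k = 13 and
multiplicity ≥ 3: with repeat-family copies diverging ~5% from their
consensus, longer or rarer k-mers leave a substantial fraction of repeat
bases unmasked (k=15/mult≥5 recovers only ~0.34 of a genome built at 0.39),
while 13/3 recovers the built fraction to within half a percentage point at
a false-masking cost of ~0.7% on a repeat-free genome.  Masking is soft:
sequences keep masked bases (lower case in FASTA), seeding skips them,
extension crosses them.  BESs with fewer than 30 bp of unmasked sequence in
total are excluded from mapping (the 30 bp need not be contiguous).

## Synthetic data

The generator emulates an AA-genome rice chromosome at desk scale.
Defaults: 2 Mbp, 170 genes (≈85 genes/Mbp, the density implied by ~32,000
genes in a 382 Mbp genome), GC 0.44, target repeat fraction 0.39, four
repeat families (unit lengths 200–3000 bp) whose copies diverge 5% from a
family consensus and are laid out as tandem-and-dispersed arrays, and one
12-member tandem gene family standing in for a clustered disease-resistance
(NBS-LRR-type) family.  Genes are in-frame coding sequences (ATG + random
sense codons, no internal stops) so the codon-extraction stage is well
defined on the reference.

Lineage divergence applies, in order: large segmental deletions (merged
when overlapping; an error if they would cover the whole genome), small
indels, then uniform substitutions to a random different base.  Genes
overlapped by a deletion even partially are dropped from the derived
annotation and logged as lost — a partially deleted gene can no longer be
detected intact.  Small indels are placed outside gene bodies (purifying
selection keeps coding regions in frame); divergence inside genes is
substitution-only.  The event log keeps deletion intervals in ancestral
coordinates, the set of deleted gene ids, and the realized substitution
count.

BAC clones draw insert lengths from a Normal truncated below at twice the
maximum end length (default 120 kbp ± 15 kbp at pipeline level); end reads
(300–800 bp uniform by default) are the subsequences at the clone
boundaries, the distal one reverse-complemented.  Single-end "simulated
BES" fragments are sampled uniformly with a Mersenne-Twister generator,
reject fragments containing ambiguous bases, and optionally inject
substitutions at a per-site rate (0.025 in the validation, the average
nucleotide divergence the method is expected to absorb).

What the simulator does *not* model: transposon amplification dynamics,
recombination, selection beyond the indel placement rule, rearrangements,
sequencing error profiles, cloning bias, and assembly gaps.  Passing tests
therefore show that the estimators and the mapping machinery behave
correctly when their assumptions hold, not that those assumptions hold in
any particular real genome.

In synthetic mode, protein homology of a BES is ground truth: a BES "has
homology" when its true source interval overlaps a gene of its own genome
by more than 50 bp.  This separates the estimator from any homology-search
engine.  The same 50 bp rule drives the `N_pc`/`J_pc` counts, there applied
to placements on the reference gene track.

## Molecular evolution

Shared-codon extraction piles up the deduplicated placements of every taxon
on the reference, keeps codons whose three positions are covered in all
taxa, and drops a gene entirely when any taxon shows an internal stop codon
(ambiguous bases likewise exclude the gene).  Retained codons are
concatenated per taxon.

Nei–Gojobori counting: per codon position, the synonymous fraction of the
three possible changes; changes producing stop codons count as
nonsynonymous, so synonymous plus nonsynonymous sites equal exactly 3 per
codon; sites are averaged over the two sequences.  Differences average
synonymous/nonsynonymous steps over all minimal substitution pathways,
excluding pathways through stop codons (when every pathway is blocked, all
are used).  Proportions are Jukes–Cantor corrected; a proportion ≥ 3/4
raises `UndefinedDistanceError` rather than clamping.

K2P distances use third codon positions only, `d = −½ ln((1−2P−Q)√(1−2Q))`,
with saturation signalled the same way.  Trees are Saitou–Nei
neighbour-joining (via scikit-bio); bootstrap resamples alignment columns,
recomputes distances and counts bipartitions, normalizing by the number of
replicates whose distances stay in the model's domain.  Saturated
replicates carry no topological signal and are skipped.

The loss-rate regression fits a least-squares line *through the origin* to
the (synonymous distance, lost genes) points of the relative species — the
null model "constant loss rate" forces a zero intercept, and three points
cannot support a free-intercept test.  The free-intercept fit is reported
alongside for inspection.  The held-out near-origin points (the recently
split cultivar pair) are flagged as accelerated when they sit above the
line by more than twice the root-mean-square residual of the fitted points.
Divergence timing uses `T = d_S / (2μ)` with μ = 6.5 × 10⁻⁹ substitutions
per synonymous site per year by default (a standard rice estimate).

## Enrichment

Best homologies per BES: lowest E-value below 10⁻¹⁰ (strict), ties by
higher identity then protein id.  Among unmapped BESs the top 5% by
amino-acid identity are excluded ("possibly mapped": near-perfect protein
matches suggest the locus exists but lies in an unsequenced part of the
reference); exactly ⌊0.05·n⌋ records go, ties broken by BES id, and the
realized cutoff is reported.  Contingency tables are built over distinct
best-hit proteins, after removing proteins in transposon GO categories
(GO:0003964, GO:0004803).  Fisher's exact test reports both the one-sided
(domain overrepresented among unmapped) and two-sided p-values, since
published per-domain tables do not state a convention; for the benchmark
NB-ARC table both round to the same value.  Category-profile comparisons
use per-category two-sided Fisher tests with Bonferroni correction across
categories.

## Validation experiments and problem sizes

- *Self-mapping*: 10,000 fragments (300–800 bp) from a 2 Mbp genome at 39%
  repeats, unmutated and at 0.025 substitutions/site, aligned back without
  masking restrictions (this measures raw aligner sensitivity, not the
  pipeline filters); ≥ 99.9% must classify as mapped.
- *Parameter recovery*: 3 Mbp ancestor with 300 genes; the reference
  lineage suffers two 60–100 kbp deletions (≈5% of the genome, the regime
  the estimator is designed for, with deletions larger than the BAC
  inserts); the relative diverges at 0.025 substitutions/site; 10,000
  clones with 50 ± 7 kbp inserts.  Across five seeds the mean conservative
  `n_u` must land within 15% of the true deleted-gene count; with zero
  deletions it must stay below 2% of the gene total.
- *Oracle equivalence*: the aligner against a pure-Python Smith–Waterman on
  small references; Nei–Gojobori against exhaustive pathway enumeration;
  Fisher p-values against exhaustive hypergeometric summation; NJ against
  additive-matrix recovery and an exhaustive minimum-evolution search on
  five taxa.

These sizes keep the default test run in the tens of minutes on one core;
they are stated here as the package's validation conditions.

## Known limitations

- The `n_g`/`n_u` estimators inherit the unmapped-fraction dilution
  discussed above; they are not recommended when a large fraction (≫10%)
  of either genome is lineage-specific.
- The aligner has no E-value model; significance of a hit is carried
  entirely by the identity/coverage thresholds.
- Bootstrap supports on very short third-position alignments are dominated
  by resampling noise; the pipeline reports them but draws no conclusions
  from supports under ~50%.
- Real mode consumes precomputed homology and domain tables; the package
  never invokes external search tools, so its results are only as good as
  those inputs.
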