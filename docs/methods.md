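# Methods

This note documents the models and algorithmic choices behind
`microhic`: what the synthetic generator simulates (and deliberately
does not), how each analysis stage works, which parameters matter, and
the package's known limitations.

## The synthetic Hi-C generator

The generator produces a genome, annotation and contact data with full
ground truth, emulating Hi-C of a compact multi-chromosome fungal
genome in a Rabl nuclear configuration.

**Genome.** Defaults: 8 chromosomes spread over 1.8–5.9 Mb (jittered
deterministically per seed, snapped to bin width), one centromere per
chromosome placed uniformly in the central 30–70% span (default width
30 kb), telomeric regions defined as the outer 40 kb. Sequence is
i.i.d. at a stated GC fraction (default 0.5) with (TTAGGGG)n planted at
5' ends and its reverse complement (CCCCTAA)n at 3' ends (5 copies;
one 3' end can be omitted to emulate an incomplete assembly). Genes
(default 100 per Mb, 1.5 kb long, random strand, log-normal expression)
are placed non-overlapping with 1.5-kb promoter clearance from
chromosome edges.

**Domains.** Chromosome arms (either side of the centromere) are tiled
by self-interacting domains with sizes uniform over 2–80 kb; between
consecutive domains sits a single junction bin — the planted boundary.
Boundary bins and the centromere interval carry no domain label.

**Cis intensity.** For bins i <= j on one chromosome at bin distance
d = j - i:

    lambda_ij  ∝  (d + d0)^(-alpha) · beta^[same domain] · loop fold

with alpha = 1 (a convention; the source study does not report its
decay exponent), d0 = 1 bin, intra-domain boost beta = 2, and an
optional list of loop pairs each multiplying its pair's intensity by a
fold factor (default 8 when loops are requested).

**Trans intensity.** A three-component read-mass mixture:

* a uniform background over all trans pairs carrying eps = 0.02 times
  the total cis weight;
* a centromere-bundling component carrying k_c (default 4) times the
  uniform component's mass, spread over the products c_i·c_j of
  per-bin centromere weights (1 inside the interval, 0.5 on the single
  flanking bin, 0 elsewhere);
* a telomere component, k_t (default 2) times the uniform mass, spread
  over t_i·t_j.

Equivalently lambda_ij ∝ u + k_c·S_c·c_i·c_j + k_t·S_t·t_i·t_j with
normalizers S that fix the component mass ratios at 1 : k_c : k_t.
Mass normalization (rather than a per-pair multiplicative boost) was
chosen so that (a) the trans read share, eps·(1+k_c+k_t)/(1+eps·(1+k_c+k_t))
≈ 12% at defaults, is independent of bin size and keeps cis dominant at
every working resolution, and (b) bundled reads are concentrated enough
that per-bin trans profiles peak sharply at centromeres — the
phenomenology centromere calling and aggregate-map classification rely
on. A per-pair (1 + k_c·c_i·c_j) form was evaluated and rejected: with
narrow centromeres it perturbs per-bin trans totals by only a few
percent, making trans-based centromere detection impossible at any
realistic depth.

The whole field is scaled so the expected total count equals the
requested read number N (default 10^6); counts are independent Poisson
draws given lambda (no over-dispersion; real Hi-C also carries
coverage, mappability and restriction-site biases that the generator
does not model — recovery results here therefore bound what raw-count
methods can do on clean data, not on real libraries). Replicates are
independent draws from one intensity field. Internally the cis field is
stored as per-chromosome distance bands and the trans field is sampled
by Poissonization of the exact mixture, so the full bin-pair matrix is
never materialized; `lambda_at(i, j)` evaluates any pair exactly.

**Motif planting.** Exactly round(f·B) of the B boundary bins (default
f = 0.6) receive one copy of a 12-bp consensus at a uniform offset
within the bin; the chosen boundary ids are recorded as ground truth.

Determinism: every generator consumes a `numpy` SeedSequence derived
from the user seed and a fixed stream key, so identical seeds give
byte-identical outputs.

## Analysis stages

**Decay curve.** Off-diagonal cis reads are stratified by bin distance
(optionally geometric strata, 8 per decade). Two normalizations are
reported: the per-pair contact probability (stratum reads / possible
pairs / total cis reads), used for log-log slope fits, and the stratum
mass fraction, which sums to 1. On default simulations the fitted slope
recovers -alpha within ±0.1.

**Reproducibility.** Per chromosome, both cis matrices are restricted
to bins with nonzero degree in either replicate, row-normalized, raised
to the t-th power (t = 3, the upper end of the published random-walk
method's sweep, fixed rather than optimized), and compared by
elementwise L1 distance divided by the retained bin count; the score is
the chromosome mean of 1 - d/2 clipped to [0, 1]. It is exactly 1 for
identical matrices and invariant to global count scaling.

**Insulation and boundaries.** raw(i) is the mean count in the square
{i-w..i-1} × {i+1..i+w} (w = 10 bins by default; the source pipeline's
window is unpublished, and 20 kb at 2-kb bins sits in the conventional
insulation-window range). Squares are never truncated: bins within w of
a chromosome end are masked invalid. The track is log2(raw / chromosome
mean of raw) — per-chromosome normalization because coverage differs
between chromosomes. Boundary calling first smooths the track with a
5-bin centered moving average (noise control at realistic depth;
disable with `smooth_bins=1`), then takes local minima (plateaus
resolved to the leftmost bin; run-edge minima discarded) whose strength
— min(rise to left flanking maximum, rise to right flanking maximum) —
is at least 0.1 log2 units. Globules are the intervals between
consecutive boundary bins (boundary bins excluded), closed at
chromosome ends. On 20 default simulations the planted-boundary F1 at
±1 bin is ≈ 0.82 (noise-limited; ≈ 0.96 on the noise-free rounded
intensity field). The boundary "region" for gene/motif assignment is
the single boundary bin.

**Contact significance.** The cis prior is fitted Fit-Hi-C-style in one
pass: distances grouped into up to 100 contiguous equal-occupancy
strata (approximately equal summed reads), stratum probability =
(stratum reads / total cis reads) / possible pairs, monotonized by
weighted isotonic regression over stratum midpoints, interpolated
piecewise-linearly (clamped outside the midpoint range), and
renormalized so the expectation over all possible off-diagonal cis
pairs is 1. The published tool's second refinement pass (outlier-bin
removal) is deliberately omitted — validation here is
calibration-based, not count-matching. Each observed pair (k >= 1; the
diagonal is excluded) gets the exact binomial upper tail
P(Bin(N_cis, p(d)) >= k) via `scipy.stats.binom.sf`, and BH q-values
over the tested pairs. Trans pairs are tested separately against the
uniform prior 1/(#possible trans pairs) with N = total trans reads.
Filtering keeps q <= 0.01 and k >= 3 ("reads > 2") by default. Under
null resampling from the fitted prior at 10^6 reads the empirical
type-I error at p <= 0.01 is ≈ 0.009; with 50 planted 8-fold loops the
realized FDR at q <= 0.05 is ≈ 0.03 with ≈ 100% recall. Note the
uniform trans null means any genuine trans structure (e.g. Rabl
bundling) is called significant wholesale; on Rabl genomes the trans
calls are best read as "bundled far above uniform expectation".

**Centromere calling.** Per-bin trans totals (each pair counted at both
ends) are smoothed by a 5-bin centered moving average; bins within
max(2 bins, 40 kb) of chromosome ends are excluded (the source study
removes "ends" without giving a width) — this masks the telomeric trans
peaks that would otherwise compete. The call is the contiguous
non-excluded run around the (leftmost) argmax whose smoothed value
stays >= 50% of the chromosome maximum, reported in bp. A chromosome
whose peak-to-median ratio is below 2 gets a flatness warning (the
k_c = 0 negative control flags all chromosomes). Both raw and smoothed
profiles are retained for inspection. At 20-kb bins and default
parameters, called midpoints land within ±1 bin of truth for ~100% of
chromosomes over 20 seeds.

**Aggregate chromosome analysis.** Each chromosome is split at its
centromere midpoint bin; each arm is rescaled to F = 20 slots by
linear-overlap averaging (arms shorter than F bins are averaged, never
interpolated beyond data). For every ordered chromosome pair and both
presentations of each chromosome — forward, and reversed (the rescale
operator built on swapped arm lengths with the bin axis reversed) — the
contact block is accumulated into a 2F × 2F map with centromere slots
adjacent at the center; the map is then symmetrized. This orientation
sweep makes the map exactly invariant to chromosome input order and to
reflecting any chromosome (property-tested to 1e-9). Corner scores are
computed on the trans-only aggregation (intra signal would otherwise
dominate): cen = mean of the central 2k × 2k block (k = 3; the map
center falls on a slot edge, so a k × k block cannot be centered
there), tel = mean of the four k × k corner blocks, each divided by the
whole trans-map mean; a flat map scores 1. Classification: cen score
>= 1.5 (inclusive) ⇒ Rabl type I. At defaults the cen score is ≈ 10
and the tel score ≈ 15; the tel/cen ordering is a function of region
widths (the default telomeric regions are ~2× wider than a centromere
half-width, so slot averaging dilutes the cen signal more), not of
k_c vs k_t, and is not treated as a diagnostic.

**3D embedding.** Wish distances delta = c^(-1/3) on observed
off-diagonal pairs (exponent 3: the convention that counts scale as
spatial distance^-3, matching the referenced MDS software's default;
exposed as a parameter), rescaled so the median adjacent-bin distance
is 1. No matrix balancing is applied anywhere in the pipeline — the
significance model consumes raw counts, and the embedding consumes the
same. The embedding minimizes sigma(X) = sum w_ij(||x_i - x_j|| -
delta_ij)^2 with w = delta^-2 over observed pairs only (missing pairs
are not imputed as far), by SMACOF majorization with the weight
Laplacian pseudo-inverse precomputed; stress is non-increasing at every
iteration by construction and the iteration stops at relative stress
change < 1e-6. The start is deterministic: classical scaling on
shortest-path-completed distances (largest connected component only,
flagged otherwise), so results are seed-independent; the seed only
drives the random draws inside `structure_metrics`. Exact Euclidean
inputs (a 50-point helix) are recovered to Procrustes RMSD < 1e-15.

An intrinsic limitation worth stating: with alpha = 1 decay the cis
wish metric is delta ∝ d^(1/3) — a space-filling (fractal-globule-like)
metric that is not exactly realizable in 3D. Embedding an exact,
noise-free d^(1/3) chain caps the Pearson correlation between embedded
and wish distances at ≈ 0.89 regardless of optimizer (an independent
unweighted SMACOF gives the same picture), and on sampled Rabl data —
where the uniform-background trans pairs all share one expected count
and hence carry no geometric signal — the correlation is ≈ 0.67–0.80.
The structure is still informative at the organizational level: the
centromere clustering ratio (mean pairwise distance among centromeric
bins over a 100-draw random-bin-set null) drops to ≈ 0.24 on Rabl
simulations, and per-chromosome clothes-pin scores (centromere-centroid
to telomere-centroid distance over the chromosome's radius of gyration)
are reported per chromosome.

**Motif scanning.** PFM counts get a pseudocount of 0.25 per cell
before normalization. The background is 0-order, estimated from the
scanned sequence (uniform available as an option). Window scores are
sums of per-position log2 odds discretized to a 1e-3 grid; the null
score distribution under the background is computed exactly by DP
convolution over positions, and the observed windows use the same
discretized scores, so p-values are exact on the grid (verified against
exhaustive 4^w enumeration for w <= 6). Both strands are scanned;
windows containing non-ACGT symbols are skipped; scanning is invariant
to FASTA case and line wrapping. No multiple-testing correction is
applied to hits (mirroring default FIMO usage); the default reporting
threshold is p <= 1e-4. Boundary enrichment is the descriptive
proportion of boundary bins containing >= 1 hit (>= 1 bp overlap),
ranked descending with ties broken by motif id. Note the chance
containment rate per 2-kb boundary at p <= 1e-4 is ≈ 1-(1-1e-4)^(2·1989)
≈ 0.33, so a motif planted in 60% of boundaries surfaces at a
proportion of ≈ 0.6 + 0.4·0.33 ≈ 0.73 — the planting fraction plus
chance inflation, which the validation accounts for. Promoters are the
1.5 kb upstream of the 5' gene end on the gene's strand, truncated at
chromosome edges; unstranded genes are skipped with a warning.

**Gene annotation.** A gene is `boundary` / `interior` / `spanning`
according to the classes of the bins it overlaps (edge-masked bins are
ignored for the label). A significant contact is assigned to every gene
overlapping either anchor bin by >= 1 bp; per-gene distinct-contact
counts by kind feed the hub ranking (descending count, ties by gene
id). Telomere detection searches the outer 5 kb of each chromosome for
>= 3 tandem repeat units (forward unit at 5' ends, reverse complement
at 3' ends).

## Pipeline and problem sizes

`run-all` executes simulate → bin → decay → reproducibility →
insulation → globules → significance → centromeres → ACA → embed →
motif scan → annotation → telomeres, writes all intermediate files
plus a manifest and a JSON report, and is byte-reproducible under a
fixed seed (timestamps appear only in the log). The demo configuration
uses 4 chromosomes of 0.4–0.8 Mb with 4×10^5 read pairs at 2-kb bins
(10-kb for the coarse stages), which exercises every stage in seconds
while matching the genome-wide read density of the full-size default;
the validation suite and `scripts/acceptance.py` use the full-size
defaults (8 chromosomes, 1.8–5.9 Mb, 10^6 pairs) with seed counts
chosen per quantity (5–20) to keep Monte-Carlo error well inside the
asserted margins.

## Known limitations

* Raw counts throughout: no ICE/balancing, no coverage or mappability
  bias modeling, in the generator or the analyses.
* The distance prior is fitted in a single pass; no bias covariates.
* The trans significance null (uniform) is intentionally naive; on
  Rabl genomes it flags the entire bundled compartment.
* Single-level domain segmentation: no nested/multi-scale TADs, no
  directionality index.
* The embedding is a single-structure MDS model, not a
  population/ensemble or likelihood-based reconstruction, and the
  wish-distance transfer is a convention (see above for the intrinsic
  correlation ceiling it implies).
* Gene-level results depend on the >= 1 bp anchor-overlap rule; genes
  assigned per fragment midpoint would differ slightly.
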