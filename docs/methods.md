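# Methods

## The scan

`poolscan` detects selective sweeps in pooled-resequencing (pool-seq)
data from several populations. Pool-seq yields per-site read counts per
pool, not genotypes, so every statistic here is defined on read counts.

**Pooled heterozygosity.** For each window and pool, reads of the most
and least frequently observed allele are summed over the member SNPs
(ΣnMaj, ΣnMin; the major/minor orientation is decided per SNP per pool),
and

    Hp = 2 · ΣnMaj · ΣnMin / (ΣnMaj + ΣnMin)²

Hp ∈ [0, 0.5] and is invariant to uniform depth scaling. Per pool, Hp is
Z-transformed over all included windows (ZHp = (Hp − μHp)/σHp), so a
sweep appears as an extreme negative ZHp.

**Differentiation.** For every pool pair, each SNP contributes Hudson/Nei
HT − HS components computed from pool read frequencies (p̄ the midpoint
frequency, HT = 2p̄(1−p̄), HS = p1(1−p1)+p2(1−p2)); a window's FST is the
ratio of averages Σ(HT−HS)/ΣHT over informative SNPs (HT > 0, both pools
covered). No pool-size or depth bias correction is applied; small
negative window values are retained unclamped so pair means stay
unbiased. For a focal pool i, the di statistic of window w sums the
standardized pairwise values over all other pools j:

    di(w) = Σ_{j≠i} [FST_ij(w) − E(FST_ij)] / sd(FST_ij)

with E and sd taken per pair across included windows. Large di marks
windows where the focal pool is simultaneously unusual against every
other pool — lineage-specific differentiation rather than a genome-wide
depth or diversity artifact.

**Selection rule.** Windows are flagged when ZHp ≤ −4 (inclusive
boundary; configurable) or when di reaches the top 1% of its
distribution (linear-interpolation quantile; ties at the cutoff
included; the realized cutoff is always reported so other quantile
conventions can be audited). Flagged windows merge into loci when they
overlap or abut; the intersections of the two locus sets (criterion
"both") are the highest-confidence candidates. Loci are annotated with
any gene interval overlapping by ≥1 bp (half-open coordinates, so an
abutting gene does not attach).

**Breed-specific SNPs.** A SNP is private to the focal pool when its
major allele there is the alternate (alt read frequency > 0.5 by
default) while every other covered pool's major allele is the reference;
a pool with zero depth cannot vouch for a site and disqualifies it. The
search is restricted to gene bodies ± 1,000 bp (inclusive boundary) and,
optionally, to user-supplied conserved intervals.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window_size | 150,000 | bp | standard scale for livestock sweep scans; large enough for ~100 SNPs per window at typical densities |
| step | 75,000 | bp | half-window overlap; the scan requires step ≤ window so no sequence is skipped |
| min_snps | 10 | SNPs | windows below this are excluded from μ/σ/quantiles and selection — Hp and FST are unstable on a handful of SNPs |
| zhp_threshold | −4 | sd units | an extreme-tail rule: under a clean null, P(Z ≤ −4) ≈ 3·10⁻⁵ |
| di_quantile | 0.99 | — | top-1% rule on the window di distribution |
| min_alt_reads / min_depth | 3 / 4 | reads | per-site support filter; counts with depth < 4 in a pool are zeroed rather than the site dropped, so other pools keep their evidence |
| flank | 1,000 | bp | gene-proximal search radius for private SNPs |

Standard deviations are population (n-denominator) everywhere — one
consistent convention for ZHp and di standardization.

## The simulator

The generator emulates a medium-coverage multi-breed pooled
resequencing design: 8 pools, mean depth 10× (Poisson per site per
pool), ~1 SNP per 1.5 kb (≈100 SNPs per 150-kb window), ancestral
frequencies Uniform(0.05, 0.95). Population frequencies follow the
Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.1 per
pool — mean p, variance F·p(1−p) — which fixes a testable closed form:
for two pools the genome-wide ratio-of-averages FST has expectation
(F/2)/(1−F/2) ≈ 0.0526, which the calibration test checks to ±0.005.

Sweeps are deterministic frequency pulls, (1−s)·p + s·round(p) with ties
rounding up, in the focal pool only, inside declared intervals. This
gives exact control of effect size: at s = 0.95 the focal pool's window
Hp drops ~93% below the neutral median at depth 10. The simulator does
**not** model correlated breed history, linkage/coalescent structure,
sequencing error, or mapping bias — so passing tests demonstrate that
the statistics and bookkeeping are correct and that the scan detects
frequency-pull signatures of the planted size, not that the thresholds
are well calibrated for any particular real species' demography.

## Sweep dose and the ZHp null

Because μHp and σHp are estimated from *all* included windows, heavily
swept genomes contaminate their own null. In the bundled study scenario
(analysis/01–02: one 30-Mb chromosome, ten 300-kb sweeps at s = 0.95,
i.e. 10% of the genome and ~12% of windows swept), σHp for the focal
pool is inflated ~5× over its neutral-window value, so the most extreme
swept window reaches only ZHp ≈ −3.3 and the ZHp ≤ −4 criterion fires on
nothing — although the same window would sit at ZHp ≈ −18 against the
uncontaminated null. The top-1% di rule, being a quantile, always flags
~1% of windows (4 of 400 here) regardless of how many are truly swept.
Both effects are visible in `analysis/02_scan_selection.py`, which also
runs a sparse contrast (one sweep, ~1% of windows): there the identical
pipeline calls the sweep under both criteria (min ZHp ≈ −9.3). The
lesson for real scans is that these genome-standardized statistics
assume sweeps are rare; with a 400-window genome the quantile criterion
cannot flag more than ~4 regions by construction.

## Numerical choices and degenerate inputs

- Hp is NaN when a window has zero total reads for a pool; NaN windows
  (and all min-SNP-excluded windows) are omitted from μ, σ and quantiles
  and written as `NA`.
- A constant Hp or FST series (sd = 0 to within 1e-12 relative) raises a
  "degenerate distribution" error naming the pool or pair rather than
  emitting infinities.
- MAF spectrum bins use exact integer arithmetic
  (`(20·min_count) // depth`), so boundary values like MAF = 0.05 or 0.5
  land deterministically (left-closed bins; top bin closed at 0.5).
- Interval logic is uniformly 0-based half-open; VCF positions convert
  on read. Window membership of a 1-based SNP position p is
  start ≤ p−1 < end.
- All simulation randomness flows from one `numpy` Generator seeded by
  `SimConfig.seed`; identical configs give byte-identical output files.

## Known limitations

- The FST estimator ignores unequal pool sizes and finite depth; at
  depth 10 the per-SNP frequencies are noisy, which inflates HS and
  deflates window FST slightly. The calibration test therefore uses
  exact frequencies (`emit_true_freqs`).
- "At least N alternate reads" approximates read-level support filters
  (distinct alignment start sites cannot be evaluated from counts).
- The het/hom classification is three-way (alt-fixed / segregating /
  ref-fixed); ref-fixed sites are not variants in that pool and count in
  neither class.
- Whether pair-level E[FST] and sd should be taken across windows
  (implemented) or across SNPs is a genuine convention choice; across
  windows keeps the unit consistent with every other statistic here.
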