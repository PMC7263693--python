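# Methods

This note documents the models, estimators, defaults, and numerical
choices behind `meiomap`, and what its simulation-based tests do and do
not establish about real data.

## Meiosis model

Crossovers on a chromosome of female map length *L* (cM) arise on the
four-chromatid bundle as a homogeneous Poisson process with mean
2·*L*/100 per meiosis (two chromatids of four are involved in each
crossover, so a random gamete carries *L*/100 expected exchange points).
Positions are uniform on the female map — uniformity in cM is the
definition of the genetic scale, not an extra assumption.  Each crossover
joins one chromatid of each **local parental-origin class** at its
position, chosen uniformly (no chromatid interference); choosing by
origin class rather than by physical chromatid matters once earlier
crossovers have exchanged material, and is what makes the gamete process
exactly Haldane, *r* = (1 − e^(−2d))/2, at every scale.  The test suite
cross-checks this against a closed form at 1 Morgan and against an
exhaustive strand-enumeration oracle for half-tetrad heterozygosity.

There is no crossover interference by default; an `obligate_chiasma`
flag adds one forced crossover per bundle for users who want to explore
the obligate-chiasma regime.  The choice keeps every oracle in the test
suite tractable (closed forms and small enumerations).

**Male meiosis (heterochiasmy).**  Male crossover intensity is governed
by `male_length`; positions falling outside telomeric windows covering
`male_telomere_fraction` (default 0.1, i.e. 10% of each end) are
*discarded*.  The emergent male map length is therefore
2·`male_telomere_fraction`·`male_length`: with the defaults, a 100-cM
female chromosome pairs with a ~20-cM male map concentrated at the ends,
reproducing the strong female:male ratios seen in salmonid maps.  A
consequence worth knowing: the male cM/Mb *slope* estimated from pairs
spanning the chromosome interior is far below the mean male rate,
because most interior pairs span no male recombination at all.

**Gynogenesis.**  Half-tetrad offspring retain the two sister chromatids
of one secondary oocyte (second-polar-body retention; mitotic
gynogenesis is not modelled).  Sisters are identified by shared origin
at the centromere position.  Offspring heterozygosity then equals the
second-division segregation frequency, which under this model follows
(2/3)·(1 − e^(−3d)) with *d* the marker–centromere distance in Morgans —
the enumeration oracle in the tests reproduces this closed form, and the
small-*d* behaviour is y ≈ 2d.

**Noise.**  Genotyping error flips parental-origin codes independently
at `error_rate`; missingness masks codes at `missing_rate`.  Both are
applied at the origin level and genotypes are derived from the noisy
origins; error on an allele that does not change the genotype class is
not modelled separately.  Phenotypes are a sum of per-QTL effects
(−a / d / +a for the three genotype classes) plus Normal(0,
`residual_sd`) noise; binary traits threshold the same liability.
`residual_sd_for_pve` solves the intercross variance decomposition
(V_g = a²/2 + d²/4) so simulations can target a nominal PVE.

## Marker QC

Segregation distortion is tested per informative family with a plain
chi-square against the cross-type expectation (1:1 for testcross
markers, 1:2:1 for intercross markers; no continuity correction,
df = classes − 1); a marker is removed if any family shows p below the
threshold (default 0.01).  MAF (default minimum 0.05) and missingness
(default maximum 0.3) are pooled across families; markers informative in
no family are removed.  Filters are independent predicates, so the
surviving set does not depend on application order.  One caveat observed
in simulation: because genotype counts are correlated along a
chromosome, a single unlucky segregation fluctuation can remove a
*block* of linked markers — designs near the minimum-LG-size boundary
should allow some headroom.

Thinning keeps, per RAD locus, the SNP with the smallest offset from the
restriction cut site (ties broken by lexicographic marker id).  The
LOD-position filter works per marker on its vector of LOD scores over
candidate map positions: a zero-variance vector is removed as
degenerate; a marker whose maximum raw LOD is below mean + 1·SD of its
own raw vector is removed (a switch allows applying the rule to the
normalized vector instead); and after min–max normalization, positions
with normalized LOD ≥ 0.95 are clustered, two clusters separated by more
than 25% of the vector length counting as distinct peaks and removing
the marker.

## Grouping and ordering

Two-point LOD uses the likelihood-ratio form with r̂ = min(k/n, ½),
summed over informative parents/families; pairs scored in no family are
missing, not zero.  The recombinant count is folded,
k = min(mismatches, n − mismatches), which maximizes the likelihood over
the unknown inter-marker phase — without folding, a phase flip turns
perfect linkage into LOD 0.  Linkage groups are single-linkage connected
components of the LOD ≥ threshold graph; components below `min_size`
(default 50) dissolve into singletons.  `split_to_target` re-runs the
component analysis inside the largest groups over the whole threshold
range (default 8–60) and adopts the *maximum* threshold that yields at
least two components each larger than `min_size`, until the target
count is reached; every split is recorded in an audit trail.
`join_singles` attaches singletons whose best single-linkage LOD to a
group is ≥ 10 and exceeds the second-best group by ≥ 5, applied
simultaneously per round and iterated to a fixpoint so the result is
scan-order independent.

Ordering minimizes the sum of adjacent recombination fractions (SARF):
greedy nearest-neighbour paths from random starts (default 20) refined
by 2-opt, orientation canonicalized with the lexicographically smaller
terminal marker first.  This is a deliberate replacement for multipoint
likelihood ordering; its acceptance standard is truth recovery on
simulations (order correlation ≥ 0.99 at 180 meioses and 60
markers/LG), not score equality with any external tool.  Map positions
accumulate Haldane distances d = −(1/2)·ln(1 − 2r̂) per sex, with r̂
capped at 0.49 for finiteness; the sex-averaged position is the
per-marker mean of the two maps; unique positions are counted on the
female map.  Haldane (not Kosambi) is the default to stay internally
consistent with the no-interference simulator; the conversion is exposed
if users want to swap it.

## Centromere mapping

The half-tetrad call-set filter keeps biallelic SNPs, masks genotypes
with GQ ≤ 10, and drops markers with > 30% missingness, MAF < 0.05, a
non-heterozygous mother, or an unobserved homozygote class among
offspring.  The centromere interval spans the first to last markers with
y < 0.1; an LG with no qualifying marker is reported unresolved.

RFm profiles are recombination fractions of every marker against each
terminal reference marker, *unfolded* (the maternal haplotypes are
phase-known; values above 0.5 are only reachable through noise or
mis-phasing).  Candidate centromeric regions are: the qualifying run
(RFm ≥ 0.45) reaching farthest toward the end opposite each reference,
plus every pairwise intersection of qualifying runs from the two ends
(the metacentric signature).  When a y profile is available the
candidate containing or nearest the minimum-y position wins — the
"lowest y" disambiguation rule; otherwise intersections take precedence.
Reconciliation intersects overlapping y/RFm intervals, unions disjoint
ones with a conflict flag, and calls the chromosome metacentric when the
midpoint lies in the central 50% of the female map (a configurable
convention — real karyotype classes come from cytology, not from this
rule).

A modelling honesty note: with uniform Poisson crossovers, RFm reaches
the 0.45 cutoff only ~115 cM or more from the reference marker.  In real
salmonid females the plateau appears on ~100-cM maps because crossovers
are distally localized — a feature this simulator does not model.  The
centromere-recovery tests therefore use deliberately long test
chromosomes (300 cM telocentric, 500 cM metacentric) so the plateau is
expressed; passing them shows the estimators implement the method
correctly, not that 45 gynogens suffice on a 50-cM arm in nature.

## QTL scanning

Evaluation positions are the union of marker positions and a 1-cM grid
(deduplicated at 10⁻⁶ cM).  Genotype probabilities treat the maternal
and paternal origin chains independently: at an observed marker the
probability is degenerate; between informative flanks it is the
two-flank conditional with Haldane transition probabilities; missing
flanks fall back to the single informative side or the uniform prior.
Class probabilities (dosage 0/1/2) follow by independence and sum to one
by construction.

Kinship is the expected genotype-class identity averaged over a 3-cM
thinned grid, normalized to unit self-kinship; for full sibs with
independent uniform origins the expected off-diagonal value is 6/16.
Normal-trait scans are Haley–Knott regressions on the expected additive
(P₂ − P₀) and dominance (P₁) scores with LOD = (n/2)·log₁₀(RSS₀/RSS₁);
with kinship, one variance-component ratio is estimated under the null
by maximum likelihood in the eigenspace of K and reused for per-position
GLS (no per-position REML, no leave-one-chromosome-out).  Because the
kinship term is not LOCO, part of a strong QTL's signal is absorbed as
polygenic variance and peak LODs drop relative to the plain scan —
expected behaviour, documented rather than corrected.  Binary traits use
per-position logistic IRLS (≤ 50 iterations, fitted probabilities
clamped to [10⁻⁸, 1 − 10⁻⁸]) without kinship.

Peaks are local maxima with LOD ≥ 3; neighbouring maxima merge unless
the intervening valley drops ≥ 2 (peakdrop) below the smaller; the 95%
credible interval is the smallest position set holding 95% of the
normalized 10^LOD mass on the peak's territory, ties broken toward
lower positions so the interval always contains the peak.  Adjacent
peaks whose intervals touch carry a merge flag and are reported
separately.  Permutations shuffle trait values across individuals with
genotypes fixed; p-values are the proportion of permuted genome-wide
maxima at or above the observed LOD, floored at 1/(n_perm + 1) and
labelled "< floor" when no permutation reaches the peak.
PVE = 1 − 10^(−2·LOD/n).

## Recombination rates, homology, inversions

cM/Mb rates come from regressing pairwise |ΔcM| on |Δbp|/10⁶ through the
origin (slope = Σxy/Σx²) over pairs of markers sharing a linkage group
and a reference chromosome, with mapping quality ≥ 60 and reference
chromosomes holding more than 50 such markers; each of 100 replicates
samples 100 pairs without replacement (markers may recur across pairs)
and the mean and SD over replicates are reported per sex.  Absolute
differences make the estimator orientation-free.  Homology requires ≥ 50
qualifying loci; smaller counts are reported as suggestive.  Inversion
candidates are maximal same-direction runs of the (cM, bp) scatter
(single-marker flickers absorbed into the longer neighbour, runs
validated at |Spearman ρ| ≥ 0.9); runs opposing the edge-weighted
majority orientation with ≥ 10 markers are reversed segments, and a
segment is pericentric iff it overlaps the centromere interval with
closed-interval (boundary-touching) semantics — the conservative reading
of "overlap".  This detector formalizes what is usually a manual
dot-plot inspection; it is validated on constructed fixtures with known
breakpoints (recovered within one marker spacing), never against real
genome alignments.

## Pipeline, determinism, problem sizes

All randomness flows from one seeded generator recorded in provenance;
the same configuration and seed reproduce byte-identical outputs.  Each
stage writes a TSV plus a provenance JSON (package version, config
hash); a stage whose provenance already matches the configuration is not
rewritten.  Coordinates are cM decimals; internal physical coordinates
are 0-based half-open; VCF input follows its own 1-based standard; the
missing sentinel is "NA" in TSV and "./." in VCF.

Test problem sizes are chosen to exercise each claim at meaningful power
while keeping the default suite fast: centromere recovery uses 100
replicates of 45 gynogens × 150 markers with 358 maternal meioses;
grouping/ordering uses 10 chromosomes × 60 markers × 180 offspring; QTL
calibration uses a 200-permutation threshold against 100 null traits
(type-I checked against the exact binomial band) and 50 detection
replicates at PVE 0.15, n = 150; rate recovery uses 2000 meioses per
sex.  The full suite runs in about a minute.

## Known limitations

- No crossover interference or localization beyond the male telomere
  windows; real female crossover landscapes are not uniform.
- Kinship scans are approximate (single null variance-component fit, no
  LOCO); binary scans have no random effect.
- Parental genotypes are assumed known (no imputation) and genotype
  calling from reads/likelihoods is out of scope — inputs are hard
  calls or phase-known origin matrices.
- The inversion detector assumes a mostly collinear backbone; highly
  rearranged pairs (several interleaved inversions plus translocations)
  may fragment into unknown-orientation runs.
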