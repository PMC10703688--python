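# Methods

## The balanced genome-graph model

A rearranged tumor genome is modeled as a directed graph G = (V, E).
Vertices are strands of chromosomal segments; edges are segmental
adjacencies and come in four kinds: reference edges between genomic
neighbours, variant edges contributed by SV junction calls, loose-end
edges attached to both sides of every interstitial segment, and telomere
edges capping chromosome ends.  Every element has a reverse-complement
partner; we store each pair once, so the skew-symmetry constraint
kappa(v) = kappa(v-bar) is satisfied structurally rather than imposed.

Copy numbers kappa are non-negative integers on vertices and edges.  Mass
balance requires, at every interstitial vertex, that the vertex CN equal
the sum of incoming edge CNs and the sum of outgoing edge CNs.  Loose
ends are the slack of this constraint: a fitted loose end (CN > 0)
asserts that sequence of unexplained origin joins the segment there — a
rearrangement junction the caller did not report.

Given purity/ploidy-transformed binned read depth x, segment means
rho(v) over the bins J(v) are modeled with a Laplace likelihood with
scale b(v) = max(1, sqrt(rho(v))), and an exponential prior penalizes the
number of fitted loose ends.  The MAP estimate minimizes

    f = sum_v |J(v)|/b(v) * |rho(v) - kappa(v)|  +  lambda * #loose ends

subject to balance, skew symmetry, integrality, and kappa(e) >= 1 for
user-forced edges.  Absolute deviations are linearized with auxiliary
continuous variables and the loose-end counts with big-M indicator
binaries (M = the CN cap), so the program is a linear MIP; it is solved
exactly with HiGHS through `scipy.optimize.milp`.  A tiny per-unit reward
(1e-5) on variant-edge CN breaks ties in favour of incorporating
junctions: a copy-neutral junction (e.g. one side of a reciprocal pair)
leaves the likelihood unchanged, and without the tie-break the solver's
arbitrary choice would drop it.  The reward is orders of magnitude below
any likelihood difference, and reported objectives are always the
unperturbed f.

### Depth transform

The transform inverting the purity/ploidy mixture is
x = (r/rbar * (alpha*tau + 2(1-alpha)) - 2(1-alpha)) / alpha, where rbar
is the mean unmasked raw depth: a bin of true tumor CN c then has
expected x = c.  Negative values (possible at low depth) are clipped to
zero and counted.  SNP allelic counts are transformed per allele with the
same mixture using 1-alpha in place of 2(1-alpha).

### Pipeline

Fitting runs three MIP iterations, each followed by merging of
reference-adjacent segments whose interface carries no CN>0 variant or
loose-end edge:

1. changepoint breakpoints from depth, plus large (>10 kb) high-confidence
   junctions; clusters of reciprocal high-confidence junctions (breakends
   of two junctions within 10 kb, opposite orientation) are forced in;
2. low-confidence junctions with a breakend within 10 kb, same strand, of
   an iteration-1 fitted loose end are added and the graph re-solved;
3. a final refit adds one free continuous offset per chromosome,
   |delta_c| <= 0.3 CN, absorbed into the residual |rho - kappa - delta_c|,
   which prevents hypersegmentation from small purity/ploidy error.

Junction breakends are base-resolution and take precedence over
depth-derived breakpoints: a breakend within one bin (1 kb) of a
changepoint replaces it.  Distinct breakends always keep their exact
coordinates, even closer than one bin apart — the resulting sliver
segments overlap no depth bin and so carry no likelihood term, their CN
being determined by balance alone.  Duplicate calls of the same breakend
pair are collapsed with a warning.  Merging recomputes J, rho and b on
fused segments.  Note
that merging preserves the fitted objective exactly only when the merged
segments share their mean rho (e.g. noiseless data): with kappa equal but
rho1 != rho2 the recomputed residual of the fused segment differs from
the sum of its parts.  The pipeline always re-solves after merging, so
this has no effect on results.

### Segmentation

Pre-segmentation is recursive changepoint detection on the transformed
depth: each interval is split either at the best single changepoint
(two-mean fit) or at the best embedded window of up to 200 bins (the
two-changepoint alternative of circular binary segmentation), whichever
improves a BIC criterion with penalty 4*ln(n) per changepoint.  The
embedded-window test matters: a short CN excursion inside a long uniform
interval (e.g. a 50-kb one-copy loss in a 3-Mb segment) is near-invisible
to single-split recursion but trivially found by the window statistic.
Deterministic for fixed input.

### Parameters

- `lam` (loose-end penalty), default 15.  Calibrated on seeded benchmark
  simulations: a loose end costs roughly the residual of mis-fitting a
  20-30-bin segment by one copy.  Larger values suppress loose-end
  recovery of withheld junctions below ~150 kb; smaller values admit
  noise-driven loose ends.
- `cn_cap`, default max(10, ceil(3 tau), ceil(max rho)+1): bounds the
  big-M indicators tightly; amplicons above the cap are clipped.
- `offset_bound`, default 0.3 CN: keeps the chromosome offset from
  absorbing true aneuploidy (a whole-copy change is 1.0).
- changepoint penalty 4*ln(n): above the ~2*ln(n) null expectation of
  the maximal t^2, giving near-zero false splits per 20k-bin genome.
- snapping tolerance 1 kb (one depth bin); matching radius 10 kb for
  reciprocal pairs, loose-end rescue and benchmark scoring.

## Allelic balance

The balanced total-CN graph is expanded per parental homolog: two allelic
vertices per vertex, four allelic images per edge.  Constraints: allelic
vertex CNs sum to the vertex total; variant-edge images sum to the
variant's total CN with at most one image nonzero; at most one of the two
incoming (and outgoing) reference images of an allelic vertex is nonzero
("infinite sites": each junction arose once, on one homolog).  Reference
images may sum to less than the parent edge CN only by paying for
penalized allelic loose ends — which is exactly how homolog crossover
(AHR) surfaces, as a reciprocal pair of copy-neutral allelic loose ends
on distinct homologs.  Cross-homolog reference images carry a small
penalty (0.01) so that at objective ties the crossover is represented by
the loose-end pair rather than an equivalent cross-edge routing; allelic
loose ends co-located with a fitted total-CN loose end are not penalized
a second time (they restate the same missing junction).  The likelihood
uses segment-mean allelic counts in CN units with the same
max(1, sqrt(rho)) scale rule as the total fit; homolog labels are
arbitrary per chromosome, and evaluations compare allelic CN up to the
per-chromosome label swap.

Before allelic balancing, segments larger than 1 Mb with at least 10 SNPs
are re-split at changepoints of the minor allelic count vector, so that
copy-neutral LOH boundaries (which leave no total-CN footprint) become
segment boundaries.

UPD mechanism calls follow the rule: a segment with total CN 2 and minor
CN 0 is AHR-UPD if a reference-adjacent segment has total 2 and minor 1,
otherwise P-UPD.

## Mappability and homology

On desk-scale genomes, a position is base-unmappable when its k-mer
(k = 101) occurs elsewhere in the genome on either strand or contains an
N; exact duplication stands in for supplementary alignments, with a
Hamming-mismatch knob (default 0).  A position is CN-unmappable when
strictly more than 90% of bases in a 1-kb window (truncated at contig
ends) are base-unmappable.  NAHR-eligible homologous position pairs are
all 500-bp window pairs at >= 96% ungapped identity, both strand phases,
more than 10 kb apart; enumeration is seed-and-extend with per-diagonal
sliding-window verification and is tested for exact agreement with a
full diagonal scan.

A breakend pair is annotated as putative NAHR when a registered homology
row places one tract within 10 kb of each breakend with strand geometry
consistent with crossover: direct repeats pair opposite-orientation
breakends, inverted repeats pair same-orientation breakends.  (The
directional forward-strand windows of the original definition are
simplified to symmetric distance windows plus the strand-geometry test.)

Telomere-repeat classification matches three tandem copies of the G-rich
(TTAGGG) or C-rich (CCCTAA) telomere hexamer in any of the six cyclic
rotation frames on the loose end's forward strand; matching both panels
is flagged as inconsistent.  The panel is the canonical hexamer only;
"three tandem copies" reads the repeat trimer as an 18-mer, since six
cyclic permutations are only meaningful for the hexamer frame.

## The simulator

The generator emulates the study's simulation design at desk scale:

- a random phased diploid genome (default 4 x 5 Mb), het SNPs at density
  1/1500, and planted homologous repeat pairs (600 bp, 98% identity)
  registered in a homology table;
- rearrangement of haplotype walks by deletion (40%), tandem duplication
  (30%), inversion with flanking losses (15%), unbalanced translocation
  (10%) and reciprocal translocation (5%), sizes log-uniform 10 kb-2 Mb
  (upper bound set by the 5-Mb chromosomes); NAHR junctions link
  registered homologous pair midpoints at the configured prevalence;
  AHR crossovers replace one homolog's tail with the other's, leaving no
  junction; progressive UPD is a loss on one homolog followed by a
  nested gain on the other, with collar offsets log-uniform 2-300 kb;
- whole-walk gains/losses approach the target ploidy (purity ~ U(0.5,
  0.95), ploidy ~ U(1.8, 4.2) unless fixed); truth CN is read off the
  walks, junctions undone by later events are dropped from truth, and
  UPD events whose region no longer shows (2, 0) are dropped;
- emission: per-bin tumor depth is Poisson with mean proportional to
  bias * (alpha c + 2(1-alpha)), calibrated to 80x tumor / 40x normal
  per-base coverage (1-kb bins, 150-bp read-length equivalent); the bias
  factor is i.i.d. lognormal per bin (sigma 0.1, mean 1); SNP allelic
  counts are Poisson per haplotype; junctions are reported with
  probability s*alpha (s = 1) and split 85%/15% into high/low confidence.

What the generator does not emulate: correlated (low-rank,
replication-timing-like) depth bias from real normal panels, caller
false-positive junctions, germline SVs, subclonality, and microhomology
at breakpoints.  Consequently noise-driven false breakends are much
rarer here than in profiles normalized against real normal samples:
fitted precision saturates near 100% where the original study reports
82% (breakends) and 43% (loose ends).  Passing recall benchmarks on this
generator therefore says nothing about precision on real data; the
precision benchmarks here are effectively tests of the pipeline's
behaviour under clean noise.

For the UPD study (16-Mb near-diploid genomes, 1-2 AHR and 1-2 P-UPD
events per genome), background SVs are placed outside mechanism-event
territory: at this genome size the events cover a large fraction of the
genome and collisions would dominate scoring, whereas at the original
3-Gb scale they are negligible.

## Benchmarks

Breakend scoring uses greedy one-to-one nearest-distance matching within
10 kb on the same strand (ties broken by genomic order); CN accuracy is
RMSE over 10-kb bins, allelic CN up to per-chromosome homolog swap; UPD
calls match true events by >= 50% reciprocal overlap.  Problem sizes:
30 genomes of 20 Mb with ~50 junctions each for the breakend and
withheld-junction (30%) benchmarks, 50 genomes of 16 Mb for UPD, and 40
samples of 10 Mb with NAHR prevalence uniform in 0.1-10% for the NAHR
burden estimator.

The genome-wide extrapolation combines CN-mappable counts under two
proportionality principles (NAHR with homologous position pairs,
everything else with bases).  The published arithmetic carries
printed-precision intermediates forward — the NAHR density is rounded to
one significant figure before scaling by the unmappable pair count, and
the detected fraction multiplies the rounded mappable share — so the
report exposes both the unrounded chain and the printed-precision chain.
The published chain's HR burden (16.2 + 0.6 = 16.8 per genome) likewise
reflects rounded intermediates; recomputing from unrounded values gives
~17.0, and we report the rounded chain.

## Known limitations

- Precision-type benchmark targets are not attainable under this
  generator's clean noise model (see simulator section).
- P-UPD collars smaller than ~lambda*b bins whose junctions go
  undetected are flattened by the fit, so such P-UPD events are
  misread as AHR-UPD; this is the designed confusion mode of the
  adjacency rule, and its rate depends on the assumed collar-size law.
- The MIP is exact but not unique; at ties any optimum may be returned,
  so tests compare objectives and invariants, never specific assignments.
- Telomeric vertices carry no likelihood term; chromosome-end balance is
  unconstrained through free telomere edges.
- The mappability stack is for desk-scale synthetic genomes; published
  genome-scale mask tracks can be supplied as BED input instead.
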