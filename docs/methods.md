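# Methods

This note records the models implemented in `dualysin`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
benchmarks do and do not demonstrate.

## Data model and coordinates

All protein positions are 1-based and inclusive. The position of an internal
translation start site (iTSS) is the 1-based codon index of the internal
start codon on the protein coordinate system, so a start at codon 209 of a
310-residue protein yields a C-terminal product (CTP) spanning residues
209–310 (102 residues). A coding sequence (CDS) always carries its stop
codon, so `len(cds) == 3 * (len(protein) + 1)`. Translation uses the
bacterial code (table 11); the first codon of a gene — and the first codon of
a CTP — is read as Met whether it is ATG, GTG or TTG, while internal GTG/TTG
at non-start positions translate normally. Input validation is
collect-and-report rather than fail-fast: a cohort read returns every
record-level problem at once and excludes only the offending records.

## TIR scoring

The screening logic only needs *relative* initiation strengths: a candidate
must stand out against the other internal candidates of its own gene.
Full thermodynamic RBS-strength predictors model mRNA folding, standby sites
and more; reimplementing one is out of scope here, and the pipeline instead
accepts their output through TIR tables keyed by `(gene_id, codon_index)`.
For self-contained operation (and for the synthetic benchmarks) a simplified
scorer is provided:

* **SD:anti-SD duplex.** The mRNA window upstream of the start codon is
  scanned for contiguous Watson–Crick complementarity to the anti-SD core
  (default `CCUCCU`, configurable per host genus — initiation happens in the
  phage host, so the host's anti-SD is the relevant one, with a default
  fallback for unlisted genera). Runs are scored with nearest-neighbor RNA
  stacking free energies (Turner-style parameters, kcal/mol at 37 °C) plus
  the +4.09 kcal/mol helix-initiation term and +0.45 kcal/mol terminal A–U
  penalties. G·U wobble pairs are not considered. Duplexes shorter than
  4 consecutive pairs are treated as nonbinding: with the initiation penalty
  they are at best marginally stable and contribute mostly noise.
* **Spacing.** The aligned spacing (nt between the last paired base and the
  start codon) must lie in a 4–16 nt window; spacings of 5–10 nt are
  optimal, outside that a quadratic penalty of 0.25 kcal/mol per nt² applies.
  When a long complementary run ends too close to the start codon, trimming
  its 3′ end is considered, trading stacks for admissible spacing.
* **Start codon.** A bonus term orders the initiators ATG (0.0) < GTG
  (+1.0) < TTG (+2.0 kcal/mol).
* **Energy → rate.** `TIR = k · exp(−β · ΔG_total)` with β = 0.45 mol/kcal.
  `k` is calibrated once per parameter set so that a perfect `AGGAGG` match
  at 7 nt spacing before an ATG scores 10,000 relative units, which places
  strong sites in the range reported for high-TIR internal starts by
  thermodynamic predictors, without claiming numerical equivalence to any of
  them. With the default parameters this gives k ≈ 219, which is also the
  baseline score of an SD-less ATG candidate.

The scorer is deterministic and strictly monotone: lengthening a
complementary run at fixed spacing never lowers the TIR, and TIR is strictly
decreasing in ΔG_total.

## The filter cascade

The top-TIR candidate per gene (ties to the smallest codon index) passes
through four independent Boolean filters; retention is their conjunction.

1. **Outlier.** "Clearly above background" is formalized as the Tukey upper
   fence: TIR > Q3 + 1.5·IQR over all scored internal candidates of the same
   gene, with quartiles by linear interpolation. The fence is the standard
   box-plot outlier criterion, matching how TIR distributions are usually
   presented; a z-score rule (`(TIR − mean)/sd > 2` by default) is provided
   as a configurable alternative since the choice is not forced. Background
   is in-frame candidates only. A consequence worth noting: a gene with a
   single internal candidate can never pass the Tukey rule — it is its own
   background.
2. **Edge.** Starts within the first or last 20 codons fail (boundaries
   inclusive: codons 1–20 and L−19–L). 5′-proximal starts are likely
   misannotated gene starts; 3′-proximal ones would encode peptides smaller
   than even the smallest conserved domains.
3. **Domain overlap.** A start inside a conserved-domain interval
   (inclusive endpoints, so a start at a domain's first or last residue also
   fails) would generate a partial domain of doubtful stability.
4. **Tail domains.** Any hit categorized as a phage tail domain excludes the
   gene as a probable misannotated virion-associated lysin. The accession
   list ships as configuration (default: Siphovirus tail component,
   baseplate J, minor tail protein accessions) since no canonical list
   exists.

Genes with no domain annotations at all pass filters 3–4 vacuously and are
flagged in the result for auditing. Retained genes are ranked by descending
TIR with gene-id tie-break for reproducible output. The comparison between a
target and a control family reports both retained fractions and their ratio;
no significance test is attached. Printed percentages are rounded half-up to
one decimal.

## Clustering and positional consensus

Percent identity is computed from a global alignment maximizing matches
(match +1, mismatch 0, small affine gap costs), with the full alignment
length — gap columns included — as the default denominator; the shorter
sequence length is available as an alternative. The pair is put in
canonical order before aligning so that identity is exactly symmetric even
when co-optimal alignments exist. Clusters at threshold *t* are the
single-linkage connected components of the graph with edges at identity
> *t*: "over t% identity" describes a graph threshold, not a centroid
method. Because the 90% edge set is a subset of the 50% edge set, the 90%
partition always refines the 50% partition. Representatives are the longest
members (ties lexicographic); everything is invariant to input order.

Within a cluster, each member's iTSS codon is mapped to a common coordinate
to ask whether the predicted starts recur at the same relative position.
By default a star alignment onto the cluster representative is used (each
member pairwise-aligned to the representative; residues inserted relative to
it inherit the nearest upstream reference position); a precomputed multiple
alignment can be supplied instead, in which case alignment columns are used
directly. The consensus position is the modal column when more than half of
the members with a call fall within ±2 columns of it; the tolerance is
configurable, as "same relative position" admits small alignment jitter.

## Products and architectures

The FLP is the full protein; the CTP is its suffix from the iTSS codon with
the first residue forced to Met. An optional C-terminal tag (e.g. the
`PGGGSHHHHHH` hexahistidine tag used for immunodetection) is appended to
both products and included in their masses. Product masses facing
SDS-PAGE-style comparisons use average isotopic masses; monoisotopic masses
are used in the mass-spectrometry functions, where measured masses are
monoisotopic.

Architectures: *group 1* requires at least two catalytic domains with the
iTSS strictly between two consecutive ones (CTP keeps the second catalytic
domain and the cell-wall binding domain); *group 2* requires exactly one
catalytic domain lying entirely upstream of the iTSS (CTP carries only the
CWBD moiety). Anything else is unclassified rather than forced into a group.

## Gel filtration and stoichiometry

`Kav = (Ve − V0)/(Vt − V0)` with Ve required to lie within the fractionation
range. Calibration fits two standard linearizations by least squares over
≥ 3 usable standards: `log10(mass)` linear in Kav, and `sqrt(−ln Kav)`
linear in the Stokes radius (Laurent–Killander form). Because apparent
masses are conventionally estimated both directly and through the Stokes
radii of the standards, a third fit (`log10(mass)` vs Rs) is kept so both
routes can always be reported; standards at Kav = 0 are excluded from the
Rs-based fits where the transform diverges. The shipped reference standard
set (thyroglobulin 670 kDa/8.6 nm … vitamin B12 1.35 kDa/0.85 nm) carries
masses and radii only; elution volumes are run-specific inputs.

Charge-state series invert algebraically: each (m/z, z) peak gives
`M = z·m/z − z·1.00728 Da`; the mean and population spread across peaks are
reported. Stoichiometry search enumerates every integer composition
`a·m_FLP + b·m_CTP` with 0 ≤ a ≤ 3, 0 ≤ b ≤ 10 by default (bounds covering
all compositions of practical interest for these complexes) and minimizes
the absolute residual against the observed mass; ties break to smaller a,
then smaller b, and the full ranked table is retained.

## Synthetic cohorts

The generator emulates a lytic-enzyme database extract: 230–320-residue
proteins, host genera drawn from a configurable weight table (default: six
Gram-positive genera), domain layouts drawn from the two architecture
groups with real Pfam accessions plus an annotation-free class, a
control family carrying a portal-protein annotation and no planted starts,
and per-gene planted iTSSs at a configurable fraction (default 0.5, the
empirically motivated prevalence regime for this gene family).

Construction choices make truth recovery sharp rather than realistic:

* backbone codons exclude GTG and TTG, so every background candidate is an
  ATG and — after SD-motif rejection — scores exactly the baseline TIR;
  a degenerate background on which the Tukey rule cannot fire by chance;
* all ≥ 4 nt runs complementary to the anti-SD (the 4-mer submotifs of
  `AGGAGG`) are rejected from the backbone outside the planted site;
* background ATGs are confined to positions that pass the edge and domain
  filters, and at least five are guaranteed per gene, so per-gene background
  statistics are always defined and each engineered violation fails exactly
  its intended filter;
* strong planting writes `AGGAGG` at 5–7 nt spacing before a planted ATG
  (weak planting writes the ATG only), and start codons within ±4 codons of
  the planted site are cleared so the planted candidate is the unambiguous
  top;
* the generator then runs the real scorer and cascade on every gene and
  records any mismatch between intended and realized outcome as a
  *collision*, so benchmark tolerances can be stated exactly.

Consequently, passing the recovery benchmarks shows the pipeline machinery
is correct, **not** that the screen is accurate on real data: real genes
have non-uniform codon usage, GC bias, GTG/TTG starts, SD-like motifs
everywhere, imperfect domain annotations, and TIR backgrounds that are noisy
rather than degenerate. The false-positive behaviour observed on real
control families cannot be reproduced by this generator by design.

Benchmark sizes were chosen for fast, stable statistics: the planted-
fraction recovery benchmark uses 500 genes at planting fraction 0.5 with a
fixed seed and checks the retained count against the exact 99% binomial
interval after reconciling generator-logged collisions; the hand-built
attribution fixture uses 20 genes (8 retains, 3 per failure class).

## Numerical and degenerate-input conventions

* Quartiles: linear interpolation (`numpy.percentile` default).
* Equal-TIR ties: smallest codon index within a gene; lexicographic gene id
  across genes.
* Proteins shorter than twice the edge window can never pass the edge
  filter.
* An empty candidate list yields status `no_candidate`, distinct from
  `excluded`.
* Cluster ids and memberships are derived from sorted gene ids only.
* The proton mass constant is 1.00728 Da; kDa values at interfaces follow
  the one-decimal convention of complex-mass arithmetic.

## Known limitations

* The built-in TIR scorer is a deliberately minimal surrogate: no mRNA
  secondary structure, no standby sites, no G·U pairs, no genus-specific
  energy parameters beyond the anti-SD core. Its absolute values are not
  comparable across scorers; only the table-driven path should be used when
  a real predictor's output is available.
* Star alignment for positional consensus is an approximation to a full
  progressive multiple alignment; for distant members within a 50% cluster
  the mapped columns can drift by more than the ±2 tolerance.
* Identity is alignment-length-normalized; switching the denominator changes
  cluster granularity near the threshold.
* The GF linearizations are the classical ones, but other labs use other
  forms (e.g. Kav vs log M directly); both fits and their r² are exposed so
  the choice is auditable.
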