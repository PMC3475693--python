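# Methods

`pcevol` analyses the molecular evolution of the Salicaceae
*MIR482–MIR1448* polycistron: one transcript carrying two homologous
miRNA precursor hairpins (pre-miR482, 107 nt in *Populus*; pre-miR1448,
85 nt) separated by an 80-nt internal region, with 5′ and 3′ flanking
DNA.  This note describes the models and procedures implemented, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Sequence model and coordinates

All sequences are normalised to the RNA alphabet on input (`T`→`U`; the
DNA origin is remembered and restored on output), because the structural
and duplex operations are RNA-native.  Ambiguity codes other than `N`
are rejected.  Coordinates are 0-based, half-open everywhere.  FASTA
parsing and writing go through Biopython behind the `core_io` surface.

## Evolutionary distances

Pairwise distances use the Kimura 2-parameter model,

    K = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

with transition proportion *P* and transversion proportion *Q* counted
under **pairwise deletion** (sites with a gap or `N` in either sequence
are dropped for that pair).  When the log argument is non-positive
(saturation) the distance is reported as undefined (`nan`) with the
p-distance still available.  Pairwise deletion mirrors the common
default of distance software in this field; the alternative (complete
deletion) changes nothing on the indel-free simulated data used in the
tests.

Region tables report the mean and the **sample SD over all C(n, 2)
pairwise distances** per region.  These pairs are not independent; the
Welch two-sample t-test offered for comparing regions therefore inherits
pseudo-replication.  We reproduce that procedure because it is the one
the field reports, and document the caveat here rather than correcting
it.  Welch (unequal variances) is used rather than Student because
region variances differ by an order of magnitude.

The mature-sequence comparison (`best_offset_identity`) slides one
ungapped sequence against the other over every offset with an overlap of
at least half the shorter length and keeps the identity maximum; ties
prefer the smallest |offset|, then the negative offset.  Differences are
classified transition (A↔G, C↔U) versus transversion.

## RNA secondary structure

Folding is a Zuker-style dynamic programme over a deliberately minimal,
fully transparent nearest-neighbor model shipped as an editable TSV
(`pcevol/data/energy_params.tsv`):

- stacking free energies (kcal/mol, 37 °C) for the six canonical pair
  types (Watson–Crick + G:U), internally consistent under reading
  direction;
- hairpin/bulge/internal-loop penalties indexed by loop size, with
  1.75·RT·ln(n/n₀) extrapolation beyond the tabulated sizes; interior
  loops are capped at 30 unpaired nt;
- a linear multibranch penalty a + b·(branches + 1) with a = 3.4,
  b = 0.4 kcal/mol and free multiloop nucleotides;
- a 0.5 kcal/mol helix-end penalty per AU/GU closing pair;
- no dangles, no coaxial stacking, minimum hairpin loop 3 nt.

`energy_of_structure` evaluates exactly the same decomposition the DP
minimises, so `fold(s).energy == energy_of_structure(s, fold(s).structure)`
by construction, and the DP is verified against exhaustive enumeration
of all pseudoknot-free structures on sequences up to 18 nt.  `N` is
unpairable.  The O(n³) kernels are JIT-compiled (numba), which keeps
whole-polycistron folds (≈1 kb) in seconds.

No parity with any external folding program is claimed; published MFE
values for these precursors come from a different parameter set and are
deliberately not reproduced.  Qualitative structure — hairpin formation,
upper stem more stable than lower, internal-region foldback — is what
the package asserts and tests.

**Tie-breaking.**  Among co-optimal structures the DP prefers more base
pairs (implemented as an ε = 10⁻⁶ kcal/mol bonus per pair, three orders
of magnitude below the 0.1 kcal/mol parameter granularity, so it can
never override a real energy difference); remaining ties resolve by a
fixed traceback preference order (hairpin, stack, smallest interior
loop, leftmost multibranch split).  This makes folding deterministic.

**Per-position profiles.**  Each stack's energy is split equally over
its four positions; each loop penalty equally over the positions that
define the loop (closing pair, unpaired loop nucleotides, inner pair
positions for interior/multibranch loops); helix-end penalties go to the
pair's two positions.  The split convention is ours (no standard
exists); any equal-split convention preserves the invariant that
per-position contributions sum to the structure's total energy, which is
what the profile's cross-species comparison relies on.  Species are
profiled on their own folded structures, mapped through the alignment,
and summarised per column as mean ± 2·SE across species.

## Compensatory substitutions

Substitutions at structurally paired sites are counted **relative to a
designated reference sequence and its structure** (not by ancestral
reconstruction): for each reference pair (i, j) and each other taxon, a
difference at exactly one position is a single substitution, at both a
double.  A derived state is "pairing" if it is one of AU/UA/GC/CG/GU/UG
— G:U must count as pairing for the canonical C–G → U–G example to be
pairing-preserving.  Identical changes shared by several taxa are
counted once (deduplication applies to singles and doubles alike; a flag
disables it).  Sites where a taxon has a gap or `N` are skipped for that
taxon.

Expected counts use the Dixon–Hillis weights as printed constants:
singles 4 : 28 (of 32), doubles 11 : 32 (of 43).  Significance is
reported two ways, because the 2×2 construction behind published Fisher
p-values of this kind is ambiguous:

- a two-tailed Fisher exact test on [observed_pp, observed_pn] vs the
  *rounded* expected counts (Fisher needs integers);
- an exact binomial test of observed_pp out of the observed total at the
  success probability implied by the expectations (4/32 for singles),
  which avoids rounding entirely.

The binomial is the sharper and better-defined construction and is what
the closed-loop tests use.  For display, `printed_expected` reproduces
summary-table arithmetic: the pairing cell rounded half-up to one
decimal and the other cell as the complement of the observed total.

**A known bias, pinned by a test.**  Under a neutral K2P process with a
realistic transition bias (κ = 2), a single substitution in a
Watson–Crick stem pair preserves pairing with probability
(κ/(κ+2))/2 = 0.25 — twice the 4/32 weight — because transitions turn
WC pairs into G:U wobbles.  Observed/expected comparisons against the
printed weights therefore over-declare compensatory excess on data with
transition bias even without any pairing selection.  The type-I-error
simulation accordingly runs at κ = 2/3, the value at which the neutral
single-substitution pairing rate equals 4/32 exactly; the power
simulation runs at the realistic κ = 2 with coupling 0.9.  A dedicated
test asserts the κ = 2 inflation so the bias stays documented.

## Polycistron annotation

Reference precursors are projected onto a record by affine-gap local
alignment (match +1, mismatch −1, gap open −4, extend −1), both strands;
a match must cover ≥ 60 % of the reference and have p-distance ≤ 0.40
over its aligned columns (the same threshold the scanner uses).  Records
matching on the reverse strand are reverse-complemented before
annotation.  The five regions are then: 5′ flank, pre482 interval, the
internal gap between the precursor intervals, pre1448 interval, 3′
flank; they tile the record exactly.  Reference projection can shift
boundaries by a few nt in diverged species; boundary-precision claims
are limited accordingly.

The packaged default references are **synthetic** hairpin constructs
(files named `synthetic_*`): the published 20-nt mature sequences with a
perfectly complementary star arm, an AU-biased lower stem and a short
loop, at the published precursor lengths (107 / 85 nt).  Real precursor
sequences can be supplied in their place; every operation takes the
references as parameters.

## Polycistron scanning

A hit requires two homologous precursor-like regions on the same strand:

1. candidate matches of the query precursor are found by iterated infix
   edit-distance alignment (edlib), masking each match to find the next,
   on both strands, up to an edit-distance cap of 0.45;
2. two matches must lie within 2000 nt of one another (the contig
   window; no extra limit applies within one EST);
3. their mutual p-distance must be ≤ 0.40 — computed at the
   **identity-maximising ungapped offset** with ≥ 90 % overlap.  Gapped
   estimators were found to understate divergence here: hairpins are
   nearly their own reverse complement, so an affine aligner shifts one
   arm onto the other and hides substitutions in gaps (a truly
   45 %-diverged homolog measured ≈ 0.30).  Since indel evolution is out
   of scope for these regions, the ungapped estimator is the robust
   choice; the affine-gap and query-anchored estimators remain available
   as library functions;
4. both regions must pass the hairpin plausibility check.

**Hairpin criteria** (all in `ScannerConfig`): candidate length 60–400
nt; folding energy < 0; a *single stem* — the nested chain of pairs
walked through interior loops only, ending at a multibranch loop — holds
≥ 80 % of all pairs and ≥ 31 pairs (a ≥ 16-pair mature duplex plus the
~15-bp lower stem that precursor processing requires); and some 21-nt
window pairs into a single opposite arm, antiparallel, with ≤ 5 unpaired
positions, ≤ 3 consecutive, and ≤ 3 nt of partner-arm asymmetry.  The
mismatch limits follow common plant-miRNA annotation practice; the
asymmetry and stem-size limits operationalise the same practice's duplex
and processing requirements.  Under these criteria the packaged
references pass, dinucleotide-preserving shuffles of them fail, and
structure-preserving homologs at the divergences the scanner must
recover (up to 30 %) pass (see the test suite's shuffle and recall
experiments).

## Target analysis

Duplex scoring follows standard plant target-prediction practice, since
no scoring formula is published for this system: antiparallel global
alignment of the miRNA against the site with penalties mismatch 1.0,
G:U wobble 0.5, gap 2.0, all doubled at miRNA positions 2–13 (the seed),
hit threshold 4.0; all constants sit in `TargetScoreConfig`.  Sites are
mapped onto the codon frame of the annotated CDS; `site_peptide`
translates the complete codons inside the site, so a site whose first
codon boundary falls at its second nucleotide yields the published
P-loop motif MGGV(L)GK for the miR482.2 complement, and the miR1448
complement read in frame contains WEALE of the LWEALE motif (the
leading residue differs for a perfect complement; real sites tolerate
mismatches there).

Gain/loss is classified at transcript level between two miRNAs: shared,
A-only (lost), B-only (gained).  A gained transcript whose site frame
differs from the modal frame of the parent miRNA's targets is labelled
**frameshift** — the operational reading of "frameshift targeting": the
derived miRNA binds coding sequence in a different codon register than
its parent does on homologous targets.

## Phylogenetics

Neighbor joining follows Saitou & Nei with the Studier–Keppler
Q-criterion, deterministic lowest-index tie-break, and the exact
three-taxon closed form at the final join; negative branch-length
estimates are clamped to zero and counted (`tree.n_clamped`).  On
additive matrices the output reproduces all path lengths exactly, and an
independent implementation (scikit-bio) is used as a cross-check in the
tests.  Trees are dendropy objects; newick I/O and bipartition encoding
come from dendropy.

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate (K2P by default, p-distance selectable), and maps
support onto the bipartitions of the **point-estimate tree** — the way
published NJ figures display it — rather than onto a consensus tree.
Replicates with undefined distances are dropped and counted.  An
alignment without variation is flagged degenerate with all supports 0.
Outgroup rooting places the root at the midpoint of the edge inducing
the outgroup bipartition and errors if the outgroup is not monophyletic.
Concatenation joins alignment blocks by taxon id, either padding missing
taxa with gaps (`fill`) or keeping the intersection.

## Synthetic data generator

`simulate_polycistron_alignment` evolves a five-region root sequence
down a tree (default: a 20-tip star):

- region lengths default to 92/107/80/85/628 nt and per-region rates to
  0.066/0.014/0.006/0.016/0.060 — the study conditions.  Rates are
  expected *pairwise* distances: each star branch carries half;
- the two precursor blocks are designed hairpins (perfect mature:star
  duplex, AU-biased lower stem), the internal block folds back on itself
  by construction, flanks are random;
- substitutions follow K2P with κ = 2 by default, sampled per site from
  the closed-form transition probabilities;
- compensatory coupling c ∈ [0, 1]: when a stem site substitutes, its
  partner simultaneously receives a re-pairing base (uniform over
  canonical partners, G:U included) with probability c.  The default is
  c = 0 so that coupling is always an explicit experimental condition;
- truth objects (region intervals, designed structures, stem map,
  mature intervals) accompany every alignment.

`simulate_est_library` plants precursor + homolog pairs in a fraction of
random ESTs.  Homologs diverge **structure-aware** by default
(`mutate_preserving_pairs`): an exact count of sites is changed, but
stem substitutions re-pair their partners, so a 30 %-diverged homolog is
still a hairpin — as real precursor paralogs are, and for the same
reason the study documents (compensatory substitution).  Unconstrained
mutation at that divergence produces shuffles, not homologs, and is
available behind a flag.  `simulate_cds_targets` writes reverse-
complement sites into stop-free random CDSs at requested codon frames
and mismatch counts.

All generators are bit-reproducible under a fixed seed (numpy
`default_rng`).

**What the generator does not emulate:** indels (regions are compared at
fixed lengths; the long upstream deletions seen in real data are out of
scope), rate variation among sites within a region, base-composition
heterogeneity, sequencing error, and EST orientation/quality artifacts.
Passing the closed-loop tests therefore shows the estimators recover the
generating process under these idealised conditions, not that they are
robust to alignment error or indel-rich real data.

## Problem sizes in the test and acceptance suites

The suites use 20–30 taxa, precursor-scale (85–107 nt) or full
polycistron (992 nt) sequences, 100 replicates for the power/type-I
experiments, 100–200 bootstrap replicates, 20-EST libraries and ≤ 18-nt
enumeration oracles.  These sizes were chosen so each experiment's
binomial tolerances are meaningful while the whole suite stays quick to
run; all of them are parameters, not limits of the implementation.

## Known limitations

- The energy model is minimal; predicted MFE values are model-specific
  and only structure-level, qualitative conclusions transfer.
- Reference-relative substitution counting ignores phylogeny: shared
  ancestry can double-count along lineages (deduplication compensates
  only for identical derived states), and the Dixon–Hillis weights are
  an empirical prior, not the null of the generating process (see the
  κ bias above).
- The region t-test is pseudo-replicated (pairwise distances are not
  independent), as noted.
- The scanner's ungapped region comparison will overestimate divergence
  if real homologs contain indels; for indel-rich inputs use the
  provided gapped estimators and interpret thresholds accordingly.
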