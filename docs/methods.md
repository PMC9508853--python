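# Methods

## Scientific setting

Spliceosomes excise introns after recognising three signals: the 5' splice
site (5'ss, canonically beginning GU), the branchpoint (BP, an adenosine
inside a CURAY-like pentamer), and the 3' splice site (3'ss, ending in AG
with an NAG acceptor context). In *Schizosaccharomyces pombe*, the spacing
between the branch adenosine and the 3'ss is short (around 12 nt genome-wide),
and introns whose 3'ss sits unusually far from the BP depend on dedicated
splicing regulators (Sde2, Cactin/Cay1, Tls1) for efficient excision.
`bp3scan` implements the sequence-feature side of that analysis: it scans
introns for catalogue branchpoints, measures BP-to-splice-site spacings and
polypyrimidine tracts, classifies introns as factor-dependent or independent
from intron-retention measurements, compares the spacing distributions of the
two classes, and asks whether RNA secondary structure between the BP and the
3'ss shortens their *effective* distance.

## Branchpoint scanning and selection

The branchpoint catalogue holds 22 unique pentamers (a printed list of 24
with two duplicates removed); every entry carries the branch adenosine at
pentamer position 4, which is enforced when a catalogue is constructed. An
intron is scanned with a sliding 5-nt window; all occurrences are reported
(overlaps included), `N` never matches, and when several pentamers occur the
hit **closest to the 3' splice site** is selected, reflecting the
spliceosome's use of the 3'-most functional branchpoint. Ties are impossible
because positions are distinct.

If the 3'-most hit is degenerate under the active d3 convention (its branch
adenosine falls inside the terminal bases the convention excludes, e.g. a
CUAAG ending on the final base), the next hit toward the 5' end is tried;
when none remains the intron is flagged `no-bp-found`. Anomalies are always
flags, never errors.

## Distance conventions

"Number of bases in between" is ambiguous by a couple of nucleotides, so both
spacings are computed under explicit, switchable conventions (intron length
L, branch adenosine at 1-based position `branch_pos`):

| quantity | mode | definition |
|---|---|---|
| d3 | `between-AG` (default) | bases strictly between the branch A and the terminal AG: `L - branch_pos - 2` |
| d3 | `to-junction` | bases from branch A to the exon junction: `L - branch_pos` |
| d3 | `to-terminal-G` | bases strictly between branch A and the final G: `L - branch_pos - 1` |
| d5 | `from-branch-A` (default) | bases 5' of the branch A: `branch_pos - 1` |
| d5 | `hexamer-to-pentamer` | bases between the 5'ss hexamer and the pentamer: `pent_start - 7` |

Under the defaults, `d5 + d3 + 3 = L` for every intron (branch A plus the
terminal AG account for the constant); this partition is a tested invariant.
The worked 23-nt example `GUAAGUUUUCUAACUUUUUUUAG` gives branch position 13,
d5 = 12, d3 = 8.

## Polypyrimidine tracts

A tract is **at least six consecutive non-adenine nucleotides containing no
fewer than three uridines**. The default mode reports maximal such runs
(disjoint by construction; runs are clipped to the query region before
testing, and `N` breaks a run). Because per-region tract averages reported
for this kind of analysis could also arise from window counting, a sliding
`window` mode counts every 6-nt window satisfying the rule instead. Tracts
are counted in two regions per intron: 5'ss-to-BP (positions 1 to
`pent_start - 1`; optionally excluding the 5'ss hexamer) and BP-to-3'ss
(`pent_end + 1` to L).

## Dependency classification

Introns are classified from the log2(mutant/wild-type) intron-retention ratio
at 30 °C: dependent when the ratio reaches the cutoff (default 0.5 log2,
about a 1.4-fold retention increase), independent otherwise, unclassified
when the measurement is missing. The comparison is `>=` by default; sources
describing this cutoff write both ">=0.5" and ">0.5", a measure-zero
difference on continuous data, so one rule is fixed and the other available
via `inclusive=False`.

## Group statistics

Per group the package reports spacing histograms (over introns with a
selected BP; the histogram peak is the group's modal spacing, smallest value
on ties), tract means (over BP-bearing introns by default; introns without a
BP are counted in a separate `n_no_bp` stratum rather than silently dropped,
and can optionally enter the means as zero-tract members), the spacing-tail
counts (d3 >= 20, >= 30), and position frequency matrices for sequence logos.
The two groups' d3 distributions are compared with a two-sample
Kolmogorov-Smirnov test (asymptotic p-value); the KS D statistic is the
pipeline's measure of distribution shift.

Logo windows are declared, not inferred: 5'ss offsets -2..+6 with offset 0 at
the first intron base (negative offsets are exonic and resolve to nothing on
intron-only input — such columns are flagged empty, never emitted as zeros;
the window covers the diagnostic A content at intron positions +3/+4), BP
offsets -5..+3 around the branch adenosine (the pentamer plus 2 nt each
side), 3'ss offsets -6..0 from the last intron base. Populated PFM columns
sum to 1 and carry their per-column n.

## Secondary structure and effective distance

Full thermodynamic folding is out of scope; the package accepts external
dot-bracket structures (Vienna two-line files) and provides a deterministic
base-pair-maximisation fold (Nussinov dynamic program) as the internal
stand-in. Allowed pairs are AU, GC and GU; hairpin loops need at least
`min_loop` (default 3) unpaired bases; `N` never pairs. The traceback is
deterministic: closing a subinterval's 3' end with the pairing whose 5'
partner is smallest is preferred over leaving it unpaired, so reruns are
byte-identical. The fold maximises pair count, not free energy — it is a
geometric stand-in whose purpose is the bridging topology, and its pair
count is verified against exhaustive enumeration in tests.

**Effective distance** between two intron positions is defined as the
unit-weight shortest path in the graph whose edges are the backbone bonds
(k, k+1) and the base pairs (k, partner(k)), computed by breadth-first
search. The definition is a design choice made explicit here: an unpaired
segment reproduces the linear spacing exactly, every pair can only shorten
paths, and the quantity is a true metric (symmetry and the triangle
inequality are tested). For an annotated intron the folded segment runs from
the branch adenosine to the intron's 3' end, and the reported
`effective_d3` is the graph distance from the branch adenosine to the 3'ss
node implied by the active d3 convention (`linear_d3 + 1` in segment-local
coordinates), so `effective_d3 <= linear_d3` always holds.

Compensatory-mutation proposals model stem-rescue experiments: for a
substitution at a paired position, the partner receives the Watson-Crick
complement of the new base unless the post-substitution pair is already
Watson-Crick. A substitution that leaves only a G-U wobble still draws a
proposal — wobbles are accepted in structures but disfavoured as
restorations. Loop substitutions draw no proposal.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
exact ground truth. Each intron is assembled as
`GUAAGU + 5' spacer + BP pentamer + 3' spacer + UAG`; spacer lengths realise
the planted d5 and d3 targets under the default convention. Defaults (the
study conditions):

| parameter | default | rationale |
|---|---|---|
| d3, dependent group | trunc. normal N(25, 8) on [4, 60] nt | long-spacing class; brackets the ~21-nt functional threshold |
| d3, independent group | trunc. normal N(12, 4) on [4, 60] nt | the ~12-nt genome-wide average spacing |
| d5 | trunc. normal N(30, 10) on [10, 80] nt | realistic 5'ss-BP span for short fission-yeast introns; the construction needs d5 >= 9 |
| retention ratio, dependent | N(1.0, 0.3) log2 | well above the 0.5 cutoff with realistic overlap |
| retention ratio, independent | N(0.0, 0.2) log2 | centred on no retention change |
| BP motif weights | CUAAC-dominated (0.70) mix of 6 catalogue pentamers | CUAAC is the canonical branchpoint |
| spacer base weights | A/U 0.35 each, C/G 0.15 each | AU-rich intron interiors |
| PPT insertion | probability 0.5 per spacer, motif `UUCUUU` | controllable pyrimidine content (length-preserving overwrite) |

Decoy suppression: spacing targets and the motif are drawn once, then only
the spacer *content* is rejection-resampled (up to 1000 attempts) until no
catalogue pentamer sits 3' of the planted one. Because lengths are never
rejected, decoy suppression cannot distort the planted spacing
distributions — the planted d3 values follow their truncated-normal targets
exactly (tested by KS after dithering the integer counts over their rounding
interval, since a continuous-null KS applied directly to integer data would
overstate D by the largest atom mass). A flag disables suppression to stress
the closest-to-3'ss selection rule against decoys deliberately.

Datasets embed the introns in a single synthetic contig with 50-nt
uniform-composition exon spacers; alternate introns are placed on the minus
strand (stored reverse-complemented in the genome) so strand handling is
exercised end to end. `analytic_recall(mu, sd, c) = Phi((mu - c)/sd)` gives
the closed-form expected dependent-call fraction for Gaussian ratios and is
the calibration oracle for the classifier.

What the generator does **not** emulate: microarray probe-level noise and
cross-hybridisation, transcript isoforms, non-canonical splice-site
chemistry, nucleotide composition gradients along real introns, and any
correlation between spacing and retention beyond the group structure.
Passing tests therefore demonstrate the correctness of the measurement and
classification machinery under the stated statistical model, not the
biological conclusions on real genomes.

## Numerical and procedural choices

- Coordinates: GFF3 1-based inclusive on disk; intron-local positions
  1-based from the 5' end. Minus-strand introns are reverse-complemented at
  read time so all analysis runs in transcript orientation.
- `N` bases are preserved, never match a pentamer, break PPT runs, and never
  pair.
- The KS comparison uses the asymptotic two-sample statistic; groups must be
  non-empty.
- Histogram modes break ties toward the smaller spacing.
- Degenerate inputs: introns shorter than 10 nt are rejected at annotation;
  inverted PPT regions and out-of-range structure positions raise errors;
  empty groups raise rather than returning silent zeros.
- Problem sizes in the test-suite and acceptance computations — 1000 random
  sequences for scanner-oracle agreement, 200 sequences of length <= 12 for
  fold-oracle agreement, 200 introns for ground-truth recovery, 10 000 ratios
  for classifier calibration, 500 introns per group for shift detection —
  are the package's chosen verification scales; each completes in seconds.
- End-to-end runs are deterministic for a fixed config and seed; the run
  manifest records a SHA-256 hash of the canonical config, the catalogue,
  the conventions, and all class counts.

## Known limitations

- The internal fold maximises pair count and will overfold relative to a
  thermodynamic model; quantitative effective distances on real introns
  should use imported dot-bracket structures from a dedicated folder.
- Pseudoknots are not representable in dot-bracket input and are rejected.
- The retention-table reader assumes probe-to-intron mapping happened
  upstream; no probe-level processing is attempted.
- Genome-scale reproduction of published group counts requires the original
  annotation and microarray-derived table, both external downloads; the
  pipeline accepts them in real mode but ships no copies.
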