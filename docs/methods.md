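# Methods

This note records the models, parameter choices and numerical decisions
behind `pathcondense`, and what the synthetic benchmarks do and do not
demonstrate about real pathway data.

## Data model

A pathway is a named gene set; gene identifiers are opaque,
case-sensitive strings normalized only by stripping surrounding
whitespace. No symbol-to-identifier harmonization is attempted — real
multi-source integration requires a curated mapping step upstream, and
silently guessing identities would make results irreproducible. A
collection carries a gene universe (default: the union of all pathway
genes) that serves as the background population N for every exact test.
Collections travel as GMT; the description field carries
`name|source|provenance` so condensed collections round-trip through
the standard format.

## Condensation

Two pathways merge when any of the four criteria holds (overlap > 0.9;
symmetric difference of exactly one gene; a <3-gene pathway contained
in the other; overlap > 0.5 with one-sided Fisher p < 0.05). All
thresholds are strict inequalities, used exactly as printed in the
rule; they are exposed as parameters but the defaults are the
definition.

Decisions where the rule leaves freedom:

* **Merge order.** All pairs are evaluated; the pair with the highest
  overlap merges first (ties: lexicographically smaller id pair), and
  affected pairs are re-evaluated. This makes the procedure
  deterministic and, at the fixpoint level, insensitive to input order.
  Note that order *can* matter for the path taken: in a chain A,
  B = A + one gene, C = B + one gene, the highest-overlap pair (B, C)
  merges first and A then differs from the union by two genes, so the
  collapse completes only through criterion 4 — which requires a
  background universe larger than the bare union for the test to have
  any power. With realistic universes (hundreds of genes or more) the
  chain collapses fully.
* **Fisher table.** Margins |A| and |B|, observed cell |A∩B|,
  background N = collection universe size, held fixed through the run;
  the one-sided (over-enrichment) tail is used, since only an excess of
  sharing can justify a merge. The p-value is computed lazily, only
  when the overlap exceeds 0.5 and criteria 1–3 have not already fired.
* **Criterion precedence.** A merge event is labelled with the first
  satisfied criterion in order c1..c4; a one-gene-difference pair whose
  overlap also exceeds 90% (sets of ≥10 genes) is therefore labelled
  c1 even though the c2 flag is also true.
* **Surviving identity.** The larger pathway keeps its id and name
  (ties: lexicographically smaller id); absorbed ids accumulate in the
  survivor's provenance.
* **"Differ by one gene".** Read as symmetric difference 1 (one set is
  the other plus a single gene). The alternative reading that also
  accepts a one-gene swap between equal-size sets is available as
  `criterion2_mode="swap_or_superset"`.
* **Small-pathway exclusion** runs after condensation by default:
  criterion 3 needs the small pathways present so they are absorbed
  rather than discarded. A pre-filter flag exists for collections where
  tiny entries are known noise.

Complexity is O(n²) pair evaluations initially plus O(n) re-evaluations
per merge; a 160-pathway collection condenses in well under a second.

## Tagging

The vocabulary is 51 tags in seven categories (major systems, cell
cycle, genetic information processing, metabolism, development,
signaling, disease). The gene-annotation route takes a gene→tags table
as *input*: deriving such a table from an ontology involves manual
term-to-tag curation that is not reproducible mechanically, so the
package tests and applies only the assignment rule itself — a tag is
assigned when at least 10% of the pathway's genes and at least four
genes carry it, both thresholds inclusive ("at least"). Genes with
several tags count toward each. The keyword route matches lexicon
keywords in the title on word boundaries, case-insensitively, with
hyphen and slash treated as boundaries (so "HIV-induced" matches
"HIV"). The shipped starter lexicon maps "T cell" to the vocabulary's
"Immune system" tag — the natural phrase "immune response" is not one
of the 51 tags — and is meant to be extended per deployment. Title
keywords are known to over-tag (a pathway mentioning a disease in its
name is not necessarily a disease pathway); the per-assignment
provenance (method, matched keyword, gene counts) exists precisely so
downstream review can prune.

## Panel design

Ranking sorts genes by assay availability (only when annotations are
supplied), then by descending pathway count, then ascending mean size
of the containing pathways, then gene id — a deterministic total order
realizing "more pathways and smaller pathways rank higher". The default
cover is a *static* scan of that list, collecting each gene that covers
at least one uncovered pathway; an adaptive variant (`adaptive=True`)
re-scores genes on residual coverage. Greedy set cover guarantees a
solution within 1 + ln(max pathway frequency) of the minimum; the
exhaustive oracle (≤ 20 genes, lexicographic tie-break) and an
independent integer-program formulation verify this bound in the tests.

The assay-priority variant usually needs *more* genes than the
unprioritized one — assayable genes are not always the best covers —
but this is a tendency, not an invariant: promoting assayed genes
reorders the scan and can occasionally produce a smaller panel. The
tests therefore assert validity and the exact equality of both
variants when every gene is assayed, not an inequality between them.

Source-priority coverage accounting attributes each pathway to the
highest-priority tier (Tox21 > NCATS > PubChem > commercial) having an
assay for any of its genes, counting each pathway once.

## Enrichment

One-sided Fisher's exact test per pathway; p equals the hypergeometric
upper tail, computed via `scipy.stats.hypergeom.sf`, which the test
suite checks against exact integer-arithmetic tail sums on every table
with N ≤ 60 (agreement to < 1e-12; observed ≈ 4e-16). Query genes
outside the universe are dropped with a warning and the effective query
size is reported — silently keeping them is the classic enrichment bug.
Benjamini–Hochberg q-values are computed across all pathways tested;
the raw p is reported alongside.

## Spherical layout

Target distance d(a,b) = (1 − s(a,b)) · max_arc with max_arc = π, so
identical pathways coincide and disjoint ones are antipodal. "Distance
proportional to overlap" is deliberately read as proportional to
*dissimilarity*: the layout's purpose is that similar pathways sit
together. Coordinates are fitted by projected gradient descent on the
normalized stress Σ(g_ij − d_ij)² / Σ d_ij² (g = realized geodesic):
each step moves along the negative gradient, re-normalizes to the
sphere, and halves the step until stress decreases (40 halvings, then
stop) — descent is monotone by construction, and the seeded
initialization makes layouts bit-reproducible. The gradient of
arccos(x·y) is clipped at |x·y| ≤ 1 − 1e-9 to avoid the antipodal/
coincident singularity. Many mutually disjoint pathways cannot all be
pairwise antipodal, so residual stress around 0.3–0.8 is expected and
normal at scale; for small realizable target sets (e.g. three pathways
with pairwise similarity ½ → an orthonormal frame) stress converges
below 1e-6.

## Concordance

Activity overlap of two assays is the Jaccard index of their
active-compound sets; pairs with no active compound in either assay are
excluded and counted, as the statistic is undefined there. Pearson
correlation is the default ("correlation" unqualified is most commonly
Pearson); Spearman is a flag. The conditional correlation restricts to
pairs with gene sharing above 20% and is reported as NaN when fewer
than 3 such pairs exist or either variable is constant there.

## Synthetic generator

The generator defines the package's study conditions:

* universe of 1,000 genes; 100 base pathways of 5–40 genes (uniform);
  15 planted pathways in each redundancy class (60 total). Values are
  of the order of a single source database and keep every benchmark
  under a minute.
* each variant is planted on a *distinct* base, so the condensation
  fixpoint is exactly the base set and criterion labels can be scored.
  Near-duplicates (similarity drawn from (0.9, 1), realized by adding
  genes) require bases of ≥ 10 genes; one-gene variants are planted on
  bases of ≤ 9 genes so their pair sits below the 90% bar and
  genuinely exercises the one-gene criterion. The ledger's expected
  criterion is computed analytically from the planted sets,
  independently of the condensation code.
* tag structure is planted on bases without variants, on the pathway's
  least-shared genes, and verified at generation to be recovered
  exactly by the 10%/≥4 rule (no leakage into other pathways);
  infeasible plants raise rather than emit a wrong ledger.
* activity follows a single-latent-target model: 2,000 compounds (one
  latent target gene each, uniform over the universe), baseline hit
  rate 2%, plus 0.5 when the target lies in the assay's pathway —
  sizes and the 25-assay screen mirror a realistic qHTS pilot. A
  multi-target knob exists but the default is the simplest mechanism
  realizing the indicator-assay premise.
* the standard concordance scenario maps 25 assays onto a
  deterministic chain of sliding-window pathways (window 25, stride 8),
  giving graded sharing levels (≈ 0.52, 0.22, 0.02, 0) including two
  above the 20% conditional threshold. A fully random collection would
  have near-zero sharing everywhere and make the correlation
  degenerate.

Calibration, computed by the test-suite and the acceptance script, not
asserted from theory: under the null (sharing effect 0) the correlation
test rejects at α = 0.05 in ≈ 3.7–3.8% of 300–500 seeded screens
(within the 5% ± 2% band — slightly conservative because activity
overlaps of pairs sharing an assay are weakly dependent); under effect
0.5 a positive correlation is detected in 100% of 100 screens.

What passing these benchmarks does *not* show: real pathway collections
have correlated gene membership, annotation errors, and identifier
mismatches that the generator does not emulate; real screening data has
concentration–response ambiguity, assay artifacts and non-binary
activity. The benchmarks validate the algorithms' correctness and
calibration, not the biological completeness of any given collection.

## Problem sizes

Default test and acceptance runs use: 20 seeds × 160 pathways for
condensation; the full exact-test grid to N = 60 (tests) / N = 50
(acceptance script); 200 random cover instances of ≤ 14 genes; 500
null and 100 alternative concordance screens of 2,000 × 25. These sizes
were chosen to make every property measurable with comfortable margins
while keeping the whole suite interactive (≈ 15 s).
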