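# Methods

This note documents the procedures implemented in `hgtscreen`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that make runs reproducible.

## Query preparation

Genome sequences are hard-masked (repeat intervals → `N`) and translated in
all six frames under the standard genetic code; any codon containing `N`
translates to `X`. Frame peptides are split into *potential polypeptides*
(PPPs) at every stop codon **and** at runs of ≥ 10 consecutive `X`: a masked
repeat tract translates to an uninterrupted `X` run with no stops, and
without the second rule it would fuse with flanking genic sequence and push
the segment over the `X`-fraction limit. Segments are kept when they are
≥ 60 residues (`min_ppp_len`) with ≤ 10% `X` (`max_x_fraction`). Coordinates
are 0-based half-open on the forward strand everywhere in memory; GFF3 and
the 12-column hit format are converted at the file boundary.

Assembled transcripts, when supplied, are admitted by alignment coverage
≥ 0.90 and identity ≥ 0.97 (inclusive) and then translated under the same
six-frame, ≥ 60-residue rule as the genome.

## Homology scoring

Local alignment is Smith–Waterman–Gotoh with BLOSUM62 and NCBI-style affine
gaps: a gap of length L costs `gap_open + L·gap_extend` = 11 + L by default.
The aligner is `Bio.Align.PairwiseAligner` in local mode (the shifted
open/extend scores −12/−1 realise the same cost); an independent plain-python
Gotoh recurrence in the test suite checks exact score agreement. Raw scores
are converted to bits with the standard gapped-BLOSUM62 Karlin–Altschul
constants λ = 0.267, K = 0.041; all scheme parameters are configurable, and
externally computed hits in the conventional 12-column tabular format can be
loaded in place of the built-in search, so the thresholds below stay
meaningful for any engine reporting conventional bit scores.

## The h screen

For each query, `h` = bits(best donor-kingdom hit) − bits(best eukaryote
hit); a missing eukaryote hit contributes 0 bits, so a query with donor
homology and *no* eukaryote homology gets the largest possible h — the
strongest transfer signal, and the natural degeneration of the formula.
Candidates require h ≥ 30 and donor bits ≥ 100, both inclusive. The
bacterial and fungal screens run independently: the eukaryote background
always excludes Arthropoda (the host's own phylum would otherwise absorb
every real transfer), and the fungal screen additionally excludes Fungi.

Query-level candidates are merged gene-wise: every candidate overlapping a
CDS exon of an annotated gene joins that gene's locus, which keeps the
maximum-h hit pair; candidates overlapping no gene survive as intergenic
loci. Merging is gene-anchored because downstream biology (introns, fusion,
co-transfer) is defined at the gene level.

### Evidence checks

Three read-based checks annotate — never gate — each locus (gating is
available behind the CLI flag `--require-evidence`):

* **depth**: median per-bp read depth over the locus CDS divided by the
  median over the pooled CDS of the k = 2 nearest genes on each side; pass
  in [0.5, 2.0]. A zero or undefined neighbor median leaves the check
  not-assessable rather than failed.
* **mate pairs**: spans whose ends fall inside the locus and inside the
  flanking gene, counted per junction; pass when both junctions (or the one
  existing junction at a sequence end) have ≥ 3 spans.
* **RNA**: fraction of CDS bp with sense-strand coverage ≥ 1; pass at ≥ 0.5.

The bands (0.5–2.0, 3 spans, 50%) are package defaults chosen to be loose
enough that correctly assembled, moderately expressed loci pass under
Poisson-30 coverage with ≥ 95% probability, and are all configurable.

### Architecture detectors

* **Co-transfer**: consecutive candidate loci on one sequence, gap ≤ 10 kb,
  whose best donor hits share a genus. Three consecutive same-genus loci
  yield two (adjacent) pairs.
* **Fusion**: two donor hits on one gene with different subjects, each
  covering a ≥ 60-residue query segment, segments overlapping ≤ 10 residues.
  A pair is *rejected* when the two subjects are mutual homologs — when
  either subject also hits the other's segment at ≥ 50% of the pair hit's
  bit score — because that pattern is one donor family seen through two
  query segments (e.g. the exons of an intron-split gene), not two fused
  donor genes. Donor-genome adjacency, when a table is supplied, is reported
  on the call.
* **Introns**: exon count − 1 from the gene model.

## Phylogenetic validation

The candidate peptide (the best donor hit's query region of the merged
locus) is compared against all six taxon databases; the top 5 hits per taxon
with ≥ 30 bits are collected. The bit floor mirrors the reporting threshold
of any practical search engine: without it, noise-level local alignments of
entirely unrelated proteins (~20–28 bits) fill the per-taxon slots and
produce alignments that trim to nothing.

The hit set plus the candidate is aligned progressively: a UPGMA guide tree
on normalised local-alignment similarities, then profile–profile merges
under sum-of-pairs BLOSUM62 column scores with affine gaps (open 10 /
extend 1, numba-accelerated DP). Columns with gap fraction > 0.20 (strict)
are removed. Pairwise distances use the Kimura protein correction
d = −ln(1 − p − 0.2p²) over mutually ungapped columns, clamped to d = 5 at
p ≥ 0.85 (the formula's domain limit). Trees are neighbor-joining
(scikit-bio) with negative branch lengths clamped to zero; the tree builder
is an injection point for any other method with the same interface.

**Monophyly rule.** Among all bipartition sides containing the query with at
least one other leaf, every minimal-size side must contain only donor-taxon
leaves besides the query. Two refinements make the rule robust: internal
edges of numerically zero length are collapsed first (NJ resolves exact
distance ties arbitrarily; a zero-length edge is not a supported grouping),
and a tree containing only query and donor leaves passes trivially — as does
a candidate whose only collected homologs are donor-taxon records, in which
case no tree is built.

Support is the number of 100 column-bootstrap replicates (resample columns
with replacement, rebuild distances and tree, retest monophyly) in which the
grouping holds; during bootstrap, pairs with no comparable columns fall back
to the saturation distance instead of erroring. The verdict comes from the
full-data tree; support is reported, not gated (the `support_min` field is
carried for users who wish to gate). Fewer than 3 usable sequences, an
alignment that trims away completely, or a degenerate distance matrix yield
"not_assessable" — neither validated nor rejected.

## Expansion screen

Domain counts are per species the number of *distinct proteins* carrying the
domain (a domain repeated within one protein counts once); a species' total
is the sum of its domain counts. For each domain the 2×2 table is

    [[c_f, T_f − c_f], [round(mean c_o), round(mean T_o) − round(mean c_o)]]

with half-up rounding of the background means — the averaged-background
construction makes the second row a pseudo-species. p values are two-sided
Fisher exact probabilities (sum of hypergeometric table probabilities not
exceeding the observed table's), q values are Benjamini–Hochberg, and a
domain is *expanded* when q < 0.05 (strict) and the focal count strictly
exceeds every other species' count (ties fail). scipy and statsmodels
provide the test and the adjustment; the test suite checks both against an
explicit hypergeometric enumeration and the hand step-up formula.

## The synthetic-data generator

The generator emulates the statistical structure the screen assumes, as a
pure function of (config, seed):

* **Databases.** Each planted donor gene has a family in its kingdom: a
  family ancestor, the source lineage on its own short branch (0.10
  substitutions/site from the ancestor), 3 more divergent family members
  (0.15–0.35), and a two-member archaeal sister clade from a common archaeal
  ancestor at 0.50. The ladder matters: the transferred copy's closest
  relative is the true source, and validation trees contain an
  out-of-kingdom clade attaching *outside* the donor family. Archaea never
  enter the eukaryote background, so these relatives do not perturb h.
  Intrinsic genes get two metazoan homologs (0.15 and 0.30) and, for every
  second gene, an other-eukaryote homolog — enough that a decoy forced
  through validation is rejected on a real tree. The rest of each database
  is unrelated random protein.
* **Genome.** Genes (intrinsic from their own roots, transfers
  back-translated from donor sources at `donor_divergence` = 0.20) are laid
  out with random intergenic spacers, on random strands, with uniform
  synonymous codon choice. Introns (probability 0.5 per sufficiently long
  gene, 1–2 per gene, 60–300 bp, canonical GT..AG, codon-boundary insertion
  points ≥ 70 codons apart) test intron-acquisition flagging. Special
  architectures: a fusion gene concatenating two adjacent donor proteins; an
  adjacent co-transferred pair sharing a genus; a duplicated adjacent pair
  with one member truncated to 45% (successive pairs alternate the truncated
  member). Truncated-duplicate pairs are also genuine co-transfers and the
  truth table marks them so. A tandem-repeat tract is inserted every 8
  placement units and listed in the mask BED.
* **Read evidence.** Per-bp depth ~ Poisson(30); 8 mate-pair spans per
  gene–gene junction; RNA coverage of 5× over every expressed gene's CDS on
  its own strand.
* **Domain matrix.** 16 species × 200 domains, per-domain background rate
  λ_d ~ Uniform(15, 60) shared across species, counts Poisson(λ_d); 5
  planted domains draw the focal count at 4λ_d. The lower rate bound is
  chosen so the planted effect is statistically identifiable under
  200-domain FDR control — a generator that plants truth its own stated
  effect size cannot reveal would be self-defeating.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: codon-usage bias, indels in planted copies
(substitution-only by default), sequencing error and read-level artifacts,
assembly chimeras and contaminant scaffolds, paralogy within the host
genome, and UniProt-scale database breadth with its attendant heuristics.
The reference conditions (50 intrinsic + 10 planted genes, ~65 kb genome,
~200-record databases) are desk-scale by design; the pipeline's complexity
is linear in queries × database size.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; validation derives one sub-seed per candidate
(`seed·1009 + index`, mod 2³¹). Ties are broken lexically (hit sorting by
bit score then subject id; deterministic DP traceback preferences), output
tables are written in sorted order with fixed rounding, and every output
file carries the tool version, the seed, and a SHA-256 hash of the effective
configuration. Rerunning any stage with the same inputs and seed reproduces
its outputs byte for byte.

## Known limitations

* The tree stage is distance-based NJ, not maximum likelihood; it is exposed
  behind an injectable builder precisely so an ML engine can replace it.
* The progressive aligner is a straightforward sum-of-pairs implementation
  without iterative refinement; for the short, strongly related sequence
  sets the validation stage assembles this is adequate, but it is not a
  general-purpose MSA tool.
* The built-in exhaustive search is meant for desk-scale databases;
  large-scale screens should import external tabular hits.
* Evidence thresholds are heuristics with package defaults, not calibrated
  error rates; they annotate rather than decide.
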