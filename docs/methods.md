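# Methods

`coralmir` re-implements, as a tested library plus a sequence of analysis
drivers, a small-RNA study design for a non-model organism: clean a
small-RNA sequencing library, discover *bona fide* miRNAs from genomic read
stacks and hairpin folding, match them against known miRNAs, predict target
sites on 3′ UTRs by accessibility energy, and test target genes for GO
enrichment with DAG decorrelation.  Every stage is exercised end to end on
synthetic data with planted truth, so recovery and specificity are
measurable without any external download.

## Read cleaning

Reads carry per-base Phred+33 scores (a score *Q* encodes a base-call error
probability of 10^(−Q/10)).  The cascade, in order:

1. **3′ quality trim** — trailing bases are removed while the terminal base
   is at Phred ≤ 20.  The threshold is read strictly ("> 20"), so a base at
   exactly 20 goes.
2. **Mean quality and expected error** — a read is kept only if its mean
   Phred is strictly above 20 and its *expected error rate*
   (Σ 10^(−Qᵢ/10)) / len — the mean per-base error probability — is at most
   2%.  "Rate" is interpreted as a per-base mean rather than a total
   expected-error count; the 2% scale matches per-base probabilities.
   Reads containing N are dropped here: the error probability of a no-call
   is undefined.
3. **Adapter trimming** — the longest read suffix matching a prefix of the
   3′ adapter (≥ 3 nt overlap, ≤ 10% mismatches) is removed, repeating to a
   fixed point so the operation is idempotent; a symmetric 5′ rule is
   available but off by default (in single-end small-RNA libraries the 5′
   adapter precedes the sequencing primer and is never read, and a 3-nt
   minimum overlap makes false 5′ clipping non-negligible).  Because
   adapter removal can expose a low-quality base, the 3′ quality trim is
   re-applied afterwards; this leaves every emitted read satisfying all
   predicates simultaneously.
4. **Contaminant removal** — a read is dropped iff it shares at least one
   exact 21-mer (either strand) with a user-supplied rRNA/tRNA/mRNA
   contaminant set.  This replaces the original assemble-then-BLAST detour
   with a database-free filter of the same contract.
5. **Length** — reads shorter than 10 nt are dropped.

The report exposes the funnel count after each stage (monotonically
non-increasing) and, because the source protocol is ambiguous about whether
reads emptied by trimming count as "kept", both conventions (the emptied
count is reported separately).  The composition table (length 10–39 ×
first nucleotide) is the standard small-RNA library diagnostic: a 5′-U
excess in the 26–31 nt band indicates a piRNA population.

## Folding engine

Secondary structures are computed with a weighted Nussinov dynamic program:
maximise the sum of pair weights GC = 3, AU = 2, GU = 1 over non-crossing
pairings with hairpin loops of at least 3 nt.  The traceback is
deterministic (the 5′-most base pairs first, with its 5′-most optimal
partner), so identical inputs give identical structures.  This replaces a
full nearest-neighbour thermodynamic model deliberately: the *bona fide*
filters depend on pairing topology (which bases of the mature arm pair into
a single helix, where the duplex ends), not on absolute free energies, and
the simple objective is verifiable against exhaustive enumeration — the
test suite checks DP = enumeration for random sequences up to 12 nt.  The
same engine, with site bases forced unpaired, produces the constrained
folds used for target-site opening costs.  Windows folded as precursor
candidates are restricted to 30–150 nt (the animal pre-miRNA size range).

## miRNA discovery

* **Mapping** — exact, full-length, both strands, reads ≥ 18 nt.  A read
  sequence occurring at more than 5 genomic loci is discarded entirely
  (repeat shielding).  Exactness keeps a brute-force scan usable as an
  oracle; cleaned miRNA reads rarely need mismatches.
* **Stacks** — alignments are grouped per contig/strand by 5′ position
  (positions within 2 nt merge); stacks under 10 reads are dropped.  All
  positions are strand-local, so minus-strand hairpins are handled by the
  same code path.
* **Excision** — around each stack's modal read two windows are cut:
  modal 5′ + 70 nt downstream (mature on the hairpin's 5′ arm) and 70 nt
  upstream of the modal 3′ end (mature on the 3′ arm).
* **Duplex metrics** — after folding, the mature:star duplex is taken as
  the longest approximately-contiguous helix anchored in the mature arm
  (partner positions strictly descending, combined bulge ≤ 4 nt between
  consecutive pairs).  A single quasi-contiguous helix is what
  RNase-III processing produces; the scattered pairings of a random fold
  do not chain.  From it:
  - **3′ overhang**: for each duplex strand, the number of 3′-terminal
    bases extending past the partner of the other strand's 5′-most paired
    base (star-arm extent from the modal star read when star reads exist);
    reported as the maximum of the two strands, since which strand the
    published 3′-overhang figure refers to is not stated.
  - **5′-end consistency**: fraction of mature-arm reads sharing the modal
    5′ coordinate.
  - **Stem mismatches**: unpaired mature bases inside the duplex interval.
  - Read support per arm (mature / star / loop).
* **Score** — log₂(1 + mature reads) + 3·[star reads ≥ 1] + 5·(mature
  paired fraction).  This is a documented plausibility score standing in
  for a probabilistic read-signature model that is out of scope; the three
  terms reward depth, star-strand evidence (the strongest single indicator
  of Dicer processing) and stem quality.
* **Classification** — pass requires score ≥ 10, overhang exactly 2,
  5′ consistency ≥ 0.8, stem mismatches ≤ 4 and mature paired fraction
  ≥ 0.6.  A candidate failing *only* the overhang test, with an overhang of
  at most 3 and at least one known-miRNA match, is rescued into the set
  (`rescued_by_conservation`), reproducing the published exception for a
  conserved precursor with a 3-nt overhang.  The numeric thresholds for
  consistency and mismatches are conventions (the source lists the metrics
  but not the cut-offs) and are CLI-overridable.
* A hairpin is typically hit by both a mature-anchored and a star-anchored
  stack; passing candidates whose genomic windows overlap are deduplicated,
  keeping the best-scoring one.

## Conservation

Queries (~22 nt) are matched against reference sequences by an exhaustive
end-gap-free offset scan: every placement leaving at most 3 query bases
overhanging the subject is scored by mismatches over the overlap; hits with
at most 3 mismatches are kept, sorted by (mismatches, overhang).  Gaps are
not allowed (known cnidarian conservation alignments are ungapped).  The
scan is exact, so no seeding/e-value machinery is needed at these lengths.
Against pre-miRNA-length subjects the query slides along the full subject.
Conserved passers are named `<prefix>-miR-<family>` from the best hit's
miRBase-style id; novel passers are `<prefix>-miR-temp-<rank>` by
descending score.

The bundled `spi_mature_mirnas.fa` carries the 31 published *S. pistillata*
matures.  `known_mirnas_synthetic.fa` is a clearly-labelled synthetic
stand-in for the miRBase subjects (built by mutating the conserved matures
by 1–2 bases, matching the reported "~2 mismatched bases" for miR-100);
real miRBase sequences can be supplied by the user in the same format.

## Target prediction

For each transcript, the 3′ UTR is the suffix after the longest forward-
frame ATG-initiated ORF (ties to the 5′-most); UTRs under 100 bp are
discarded.  For each 7-mer seed match (miRNA positions 2–8, Watson–Crick;
6/8-mers and G:U are flags) the site score is

    ΔΔG = ΔG_duplex + opening cost

with ΔG_duplex ≤ 0 the duplex energy under the per-pair model (GC −3,
AU −2, GU −1 kcal/mol), extended outward from the seed while pairs form,
and the opening cost ≥ 0 the fold-score difference (free vs site-forced-
unpaired) of the ±70 nt context, converted to kcal/mol.  Sites with
ΔΔG ≤ −10 kcal/mol are retained.  Sign convention: the opening cost is
defined positive, so ΔΔG = ΔG_duplex + open_cost ≡ duplex energy minus a
(negative) opening free energy; ΔΔG can never undercut ΔG_duplex.  Because
the per-pair table is a simplification, the absolute kcal scale is
calibrated against the −10 cutoff by the synthetic designer, and the
cutoff is configurable.

## GO enrichment

Annotations are propagated to all is_a ancestors, then each term is tested
with the exact hypergeometric upper tail P(X ≥ k) (integer arithmetic,
floats only at the end).  Two scorings: *classic* (plain per-term test) and
*elim* — terms are processed level by level from the leaves up, and a term
significant at the elimination cut (default = α) has its annotated study
and background genes removed from all its ancestors before they are tested,
decorrelating parents whose signal is driven by one significant child.  The
published analysis used a hybrid weight/elim scoring whose mixing is an
implementation detail of one package; the elim algorithm is fully specified
and deterministic, so it is the default here, with classic always reported
alongside.  No multiple-testing correction is applied (the tests on a DAG
are strongly non-independent); the significance threshold is P < 0.01.
Terms without study annotation are reported with p = 1 rather than omitted.

## The synthetic data generator

The generator's defaults are the study conditions of every recovery check.
What it emulates, and how:

* **Hairpins** (20, one per ~460 nt contig, alternating strands): mature
  (22 nt) + loop (15 nt) + star, where the star is the complement of the
  mature reversed and shifted so that both strands carry a 2-nt 3′ overhang
  (Dicer geometry).  One hairpin is planted with a 3-nt overhang and two
  known-reference matches, exercising the conservation-rescue path; five
  hairpins are mirrored in the synthetic known-miRNA reference (families
  miR-100/2022/2023/2030/2036-style ids).  The designed helix is made the
  unique fold optimum (poly-A loop, {A,C} overhang bases, G/C
  loop-proximal pairs), and every planted window is verified by re-folding
  at generation time; draws violating the designed geometry are redrawn.
* **Reads**: per-hairpin counts are log-normal (median 200, σ 0.4) split
  ~72/25/3% across mature/star/loop; arm reads start at the designed 5′
  end with probability 0.9 (else ±1–2 nt); inserts are read on a 36-cycle
  instrument with 3′-adapter read-through, a quadratically decaying Phred
  profile (38 → 18) and Phred-driven base errors.  A 15% piRNA-like
  fraction (26–31 nt, 5′-U probability 0.9), 20% short random noise reads,
  5% contaminant fragments from a bundled ~2 kb mock rRNA/tRNA set, and
  one 22-mer planted at six loci (food for the multi-locus discard)
  complete the library.  Every read is labelled in the truth table.
* **Transcripts** (120): leader + designed 60-codon ORF + 3′ UTR ≥ 150 nt.
  Strong sites are full reverse complements of a mature in a low-structure
  {A,C} context (deep duplex, negligible opening cost).  Weak sites are
  seed-only matches locked inside a designed stem whose opposite strand is
  the seed itself, in an {A,C} context; with weak-designated seeds drawn
  from {A,C}, the constrained fold provably scores zero and the opening
  cost cancels the duplex energy, so weak sites sit at ΔΔG ≈ 0.  Each
  transcript is verified against the package's own ORF finder, UTR
  extractor and energy functions before emission.
* **Ontology**: a random is_a DAG (40 terms), genes annotated to 1–3
  non-root terms; the deepest leaf is the enriched term, carried by study
  genes at 5× the 6% base rate.  At the module's default shape (study 50,
  background 1000) the planted term is recovered at p ≪ 0.01 by both
  scorings.
* **Decoys**: 200 random windows of excision size carrying read stacks
  with the same count distribution and 5′ purity as planted hairpins —
  only the structure is missing.  Giving decoys realistic read support is
  what makes the ≤ 5% specificity bound meaningful.

What the generator does **not** emulate: realistic coral genome
composition or repeat structure, isomiR/degradation ladders, ligation
biases, instrument error models beyond per-base Phred draws, or UTR base
composition (site contexts are deliberately low-structure).  Passing the
recovery checks therefore demonstrates that the pipeline's logic implements
its stated contracts, not that its thresholds are optimal on real coral
data.

## End-to-end run and problem sizes

`run_all` chains simulate → qc → discover → conserve → targets → enrich,
writes each stage's tables under the run directory and a manifest of
checksums and row counts; identical configuration and seed give identical
checksums.  The default problem sizes (20 hairpins, ~7,000 reads, 120
transcripts, 200 decoys, 1,000-gene ontology) were chosen so a full run
completes in well under a minute per stage on one CPU while keeping every
statistical check away from its threshold; they are the package's study
conditions, not tuning knobs.

The end-to-end enrichment leg pools targeted transcripts into one study set
(~25 strong-site transcripts plus chance sites within a 1,000-gene
universe).  At the generator's effect size this leg is intentionally
marginal (expected k ≈ 7.5 vs a null of ≈ 2.7) — with some seeds the
planted term does not reach P < 0.01 there, and the drivers report whatever
it measures.  The powered recovery check for enrichment runs at the
ontology module's own default shape (study 50, background 1000).

## Known limitations

* The folding objective is maximum weighted pairing, not free-energy
  minimisation; structures agree with thermodynamic folders in topology
  for clean hairpins but not in detail, and the kcal/mol scale of ΔΔG is
  model-internal.
* Exact-match mapping ignores sequencing errors (error-bearing reads are
  simply lost, ~1–2% at the simulated error profile).
* The elim scoring is not claimed equivalent to the hybrid weight/elim
  algorithm of the original analysis.
* Per-miRNA enrichment (as in the source study) is not meaningful at desk
  scale; target genes are pooled.
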