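# Methods

This note documents the models and procedures implemented in `neoepitope`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Coding-change engine

Transcripts are modeled refFlat-style: sorted non-overlapping exons and a
CDS interval (stop codon included), all coordinates 0-based half-open.
VCF positions are converted on read, so interval arithmetic is uniform
internally.

A variant is projected into spliced CDS coordinates strand-aware
(REF/ALT reverse-complemented on minus-strand transcripts). Only clean
exonic hits are annotated: variants that are intronic, in a UTR, or span a
splice junction are classified `noncoding` and skipped with a warning —
this mirrors the exonic prioritization of standard annotators without
attempting splice-site effect prediction.

Both alleles are translated from the CDS *plus* the transcript's 3'UTR.
The wild-type stops at its stop codon regardless, so this changes nothing
for it; for stop-loss and frameshift alleles the read-through continues
into the UTR and the novel tail runs to the next downstream in-frame stop.
The tail is not capped; if no stop exists before the transcript end a
warning flags the possibly truncated tail. Translation uses the standard
genetic code only (no selenocysteine or alternative codes); codons
containing N translate to `X`, and peptides containing `X` are dropped
before prediction because binding predictors cannot score them.

Consequence classes are assigned from the protein diff:

* identical proteins → `synonymous`;
* equal-length substitution with exactly one differing residue →
  `missense` (several differing residues, e.g. from an MNV, are treated as
  a segment change and routed with the indel-type report);
* shorter mutant → `stop_gain`, longer mutant → `stop_loss`;
* indels keep their frame-derived class (`frameshift` when the length
  change is not a multiple of 3, else `inframe_indel`).

Stop-gain and synonymous variants produce no candidate peptides: a
truncation introduces no novel sequence. One consequence is produced per
(variant, transcript) pair, transcripts visited in name order; identical
(peptide, variant) candidates from different transcripts are collapsed
keeping the first transcript. Nearby somatic variants are treated
independently (no phased multi-variant peptides).

### Context windows

With maximum epitope length `L`:

* **missense** — up to `2L−1` residues centered on the changed residue,
  truncated at protein ends, with the aligned wild-type window;
* **frameshift / stop-loss** — `L−1` wild-type residues preceding the first
  changed residue plus the entire novel tail (no wild-type partner); an
  immediate stop (empty tail) rejects the context with a recorded reason;
* **in-frame indel** — `L−1` flanks around the altered segment.

The novel "core" is a half-open interval in context coordinates. A pure
in-frame deletion leaves an *empty* core at the junction; the enumeration
rule `start < core_end and start + L > core_start` then requires a window
to strictly span the junction, which unifies all classes under one
overlap test. Candidate epitopes are all L-mers overlapping the core for
each requested length (default lengths 8, 9, 10; the configurable bound is
8–14).

## Binding prediction and binder classes

Prediction is a contract: anything that deterministically maps
(peptide, allele) to a percentile rank (0–100, lower = stronger) and
optionally an affinity in nM. Three implementations ship: a TSV-backed
lookup table, an adapter for netMHCpan 4.0/4.1 plain-text output (the
eluted-ligand `%Rank_EL` column is preferred when both EL and BA exist,
matching the tool's own recommendation), and a seeded hash predictor that
guarantees only determinism and range — used for property tests at scale.

Binder classes follow the published percentile-rank convention: rank ≤ 0.5
strong binder, ≤ 2 weak binder, otherwise non-binder, boundaries
inclusive; both thresholds are configurable. In filtered mode (default)
only SB/WB rows are written; unfiltered mode keeps NB rows with their
class. Patient HLA genotypes come from a simple TSV or POLYSOLVER
"winners" files (tokens truncated to two-field resolution, e.g.
`hla_a_01_01_01_01 → HLA-A01:01`); homozygous calls collapse to a single
allele, so a homozygous haplotype is predicted once. Without a haplotype
file a configurable default set of six common European-ancestry alleles is
used (HLA-A01:01, A02:01, B07:02, B08:01, C07:01, C07:02).

## Novelty and recognition potential

Novelty is an exact substring test against the reference proteome: a
candidate occurring verbatim in any normal protein is flagged non-novel.
An empty proteome makes everything novel, with a warning.

The recognition potential is the product `A·R`:

* `A = K_d(WT)/K_d(MT)` in nM — the orientation where a mutant binding
  more strongly than its wild-type counterpart gives `A > 1`. The
  functional form (rank vs nM, orientation) is exposed in the scoring
  layer and documented because conventions differ between tools.
  Indel-type candidates have no aligned wild-type peptide; they are
  reported with `A := 1` and an `amplitude_undefined` flag rather than
  dropped, so the similarity signal survives for them.
* `R = Z/(1+Z)` with `Z = Σ_e exp(−k·(a − s_e))` over the epitope
  database, where `s_e` is the Smith–Waterman score of the candidate
  against epitope `e`. Defaults `k = 4.86936`, `a = 26`, BLOSUM62 with
  affine gap penalties 11 (open) / 1 (extend) — the configuration
  distributed with the companion recognition-potential method this model
  follows. `Z` is evaluated through log-sum-exp, so large scores cannot
  overflow; mathematically `R < 1` strictly, but the logistic saturates to
  1.0 in double precision for near-identical matches and the closed bound
  is accepted. An empty database gives `R = 0` (the no-evidence limit).
  Neither `A` nor `R` is capped before the product.

The alignment is a native affine-gap Smith–Waterman (Gotoh recursion)
rather than a call to an external BLAST binary: it removes a runtime
dependency and makes scores exactly testable against a naive DP oracle.
The gap convention is BLAST-style — a gap of length `g` costs
`open + g·extend` — matching how the 11/1 parameters are used by blastp;
scores can therefore differ from blastp output only through that tool's
compositional adjustments, not through the gap model. In filtered mode
recognition is scored for candidates that pass the novelty screen;
unfiltered mode scores everything.

## Clonality and burden

Clonality is a function of the variant's presence vector only: present in
all regions → clonal, in at least two but not all → shared, in exactly
one → subclonal; single-region inputs are clonal by convention. Presence
in a region means that region's VCF genotype contains the record's ALT
allele index; `./.` counts as absent; a missing GT field falls back to
present with a warning (conservative inclusion). This genotype rule is the
simplest one backed by the VCF itself; depth- or VAF-based presence is out
of scope. Multi-allelic sites are split into one record per ALT allele,
never jointly annotated.

Burden summaries count SB/WB candidates (non-binders never enter) over
binder × clonality, plus per-region totals. The counting unit is the
(peptide, allele) candidate by default, with a `variant` option that
counts each variant once at its strongest binder class — the published
summaries do not fix the unit, so it is exposed in config.

## Synthetic cohort and truth oracles

`fixtures.make_cohort` builds a miniature study: one genomic contig
carrying one synthetic locus per planted variant (40-codon CDS, 9 nt
5'UTR, a 3'UTR with stop codons guaranteed in all three frames; strand and
single/two-exon structure cycle across loci), per-patient three-region
VCFs with one variant of each consequence class, HLA files in both
dialects, a predictor table covering every enumerated peptide with
designed ranks for a "focus" peptide per variant (cycling SB/WB/NB across
alleles and A ∈ {10, 1, 0.1} across variants), a proteome containing all
wild-type proteins plus a subset of mutant focus peptides (planted
non-novel cases), an epitope database containing exact copies of half the
focus peptides plus random 9-mers, and a gene expression table.

The truth file records, per planted variant, the expected consequence
class, context, clonality, per-allele binder class, novelty, and
(A, R, A·R). Truth values are computed by straight-line arithmetic coded
independently of the production modules: a separate codon dictionary, a
naive explicit-gap Smith–Waterman DP, and a hand-rolled log-space
evaluation of `R`. Discrete truth fields must match exactly; `R` and the
product are compared at 1e-9 relative tolerance because the oracle and the
implementation intentionally use different float summation paths.

What the fixtures emulate: coding consequences of all classes on both
strands with and without introns, multi-region genotypes, controlled
binder classes, controlled novelty, controlled similarity. What they do
not: realistic mutational signatures, read-level noise, HLA typing error,
actual trained binding predictions, or proteome-scale novelty search.
Passing the golden run therefore demonstrates the correctness of the
plumbing and the model arithmetic under known inputs, not predictive
accuracy on real tumors — the binding predictor remains the external
scientific dependency it is in practice.

## Problem sizes and numerical choices

The test suite and the acceptance script run the cohort at 2 patients × 3
regions × 6–12 variants, 500 random oracle comparisons per consequence
class for the coding-change engine, an exhaustive Smith–Waterman oracle
sweep over all pairs of length ≤ 3 from a 4-letter sub-alphabet plus 4,000
seeded longer pairs (lengths 4–6), and 10,000 random presence vectors for
the clonality partition — sizes chosen so the whole suite completes in a
few seconds while still exercising every code path on both strands.

Determinism is a contract: fixed inputs and config produce byte-identical
outputs (floats are serialized via `repr`, so table round-trips are
bit-exact), and the run manifest hashes the configuration excluding the
output directory so the same analysis written twice is verifiably the
same run.

## Known limitations

* No splice-site, UTR, or regulatory effect prediction; junction-spanning
  variants are skipped, not modeled.
* No phasing: two nearby somatic SNVs are never combined into one mutant
  peptide.
* The frameshift novel tail is uncapped; extremely long read-throughs are
  enumerated in full.
* `A` requires affinities in nM from the predictor; rank-only predictors
  yield `A := 1` with the `amplitude_undefined` flag.
* MHC class II (15+mer) prediction is out of scope beyond the configurable
  length bound.
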