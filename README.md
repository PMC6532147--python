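# neoepitope

Neoantigen candidate discovery from single- and multi-region somatic
variant calls.

Tumors accumulate somatic mutations; the mutated peptides they translate
can be presented on the cell surface by MHC class I molecules and
recognized by cytotoxic T cells. `neoepitope` takes a directory of patient
VCFs (optionally with one sample column per sequenced tumor region), a
genome and transcript table, and patient HLA haplotypes, and produces for
every candidate (peptide, HLA allele) pair:

* the protein consequence behind it (missense, in-frame indel, frameshift,
  stop-loss — silent and stop-gain variants yield no novel peptide),
* a **binder class** from the predicted MHC-I percentile rank — strong
  binder (SB) at rank ≤ 0.5, weak binder (WB) at rank ≤ 2, non-binder (NB)
  above,
* **novelty** against a reference proteome (a candidate occurring verbatim
  in the normal proteome is not a neoantigen),
* the **TCR recognition potential** `A·R`, where
  `A = K_d(WT) / K_d(MT)` is the ratio of wild-type to mutant predicted
  dissociation constants, and
  `R = Z / (1 + Z)` with `Z = Σ_e exp(−k·(a − s_e))` weights the candidate's
  Smith–Waterman alignment scores `s_e` against a curated list of known
  immunogenic epitopes (IEDB-style) through a multistate thermodynamic
  model (defaults `k = 4.86936`, `a = 26`, BLOSUM62, affine gaps 11/1),
* the **clonality class** of the underlying variant across tumor regions:
  *clonal* (present in all regions), *shared* (in at least two but not
  all), *subclonal* (in exactly one),

plus per-patient burden summaries over binder class × clonality class.

The trained MHC-I binding predictor stays external and pluggable: use a
precomputed netMHCpan 4.x output directory (`--netmhcpan-out`), a lookup
table (`--predictor-table`), or the built-in seeded hash predictor for
testing. The toolkit is aimed at method developers and analysts who need a
fully testable, deterministic pipeline around those predictions.

## Worked example

Generate a deterministic synthetic cohort (two patients, three tumor
regions, one variant of every consequence class per patient) and run the
full pipeline over it:

```bash
neoepitope make-fixtures --seed 1 --out demo/cohort
neoepitope run \
  --vcf-dir demo/cohort/vcf \
  --genome demo/cohort/genome.fa \
  --transcripts demo/cohort/transcripts.refflat \
  --hla demo/cohort/hla.simple.tsv \
  --predictor-table demo/cohort/predictor_table.tsv \
  --proteome demo/cohort/proteome.fa \
  --recognition --epitope-db demo/cohort/epitope_db.tsv \
  --expression demo/cohort/expression.tsv \
  --unfiltered --out demo/out
```

This writes three files per patient. The burden summary
(`demo/out/P1.summary.tsv`):

```
patient	n_regions	category	binder	count
P1	3	clonal	SB	13
P1	3	shared	SB	3
P1	3	subclonal	SB	9
P1	3	clonal	WB	20
P1	3	shared	WB	12
P1	3	subclonal	WB	25
P1	3	region:R1	total	48
P1	3	region:R2	total	82
P1	3	region:R3	total	33
```

Patient P1 carries 82 strong/weak-binding candidates in total, of which 33
(13 SB + 20 WB) are clonal — present in all three regions — while region R2
carries the largest regional burden. Candidate-level rows live in
`P1.neoantigens.snv.tsv` (single-residue changes) and
`P1.neoantigens.indel.tsv` (frameshifts, in-frame indels, stop-losses),
e.g.:

```
patient	line_id	change_class	hla_allele	peptide_mt	binder_class	novel	A	R	recognition_potential
P1	1	missense	HLA-A01:01	AVLRVELH	NB	1	33.907940735808225	9.276291646549855e-20	3.1453994739928538e-18
```

Here the mutant 8-mer `AVLRVELH` is novel (absent from the reference
proteome), binds HLA-A01:01 much better than its wild-type counterpart
(`A ≈ 33.9`), but resembles no known epitope (`R ≈ 9e-20`), so its
recognition potential is negligible — a typical profile for a candidate
that would be deprioritized.

## Library layout

| module | role |
| --- | --- |
| `neoepitope.io_formats` | FASTA / refFlat / VCF / HLA (simple + POLYSOLVER winners) / expression / epitope-list readers, output tables |
| `neoepitope.coding_change` | CDS assembly, variant projection (strand-aware), translation, consequence classification, peptide context extraction |
| `neoepitope.epitope_enum` | sliding-window enumeration of 8–14-mer candidates over the mutated core, WT pairing, deduplication |
| `neoepitope.binding` | predictor contract, table/hash predictors, netMHCpan 4.x output adapter, SB/WB/NB thresholds |
| `neoepitope.recognition` | proteome novelty, native Smith–Waterman (Gotoh), partition-function similarity R, amplitude A, product A·R |
| `neoepitope.heterogeneity` | clonal/shared/subclonal classification, burden summaries |
| `neoepitope.pipeline` | orchestration, config validation, manifest |
| `neoepitope.fixtures` | synthetic cohort generator with independent truth oracles |

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
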