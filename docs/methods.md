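# Methods

## Pathogenicity rubric

The rubric combines two independent signals about a missense
substitution: how chemically radical it is, and how evolutionarily
constrained its position is.

**Grantham distance.**  The published Grantham (1974) integer matrix is
embedded as constants (`ph1kit.scoring.GRANTHAM`), symmetric with a zero
diagonal.  The test suite cross-checks the embedded table against an
independent recomputation from the published residue properties
(composition *c*, polarity *p*, molecular volume *v*, weights
α = 1.833, β = 0.1018, γ = 0.000399, scaled to a mean distance of 100):
188 of 190 pairs agree within rounding; the printed table's Asn–Glu (42)
and Asp–Trp (181) entries are known not to match an exact recomputation
and the printed values are treated as authoritative, since they are what
every annotation tool uses.

**Point bins.**  Distance bins are applied exactly as published, with
boundaries inclusive as printed: [0, 60) → 1, [60.0, 78.3] → 2,
[78.4, 93.4] → 3, (93.4, ∞) → 4.  The cysteine rule (any exchange
involving cysteine → 5 points) is checked *before* the bins and
overrides them.  The printed bins leave the open interval (78.3, 78.4)
uncovered; integer distances never land there, but a non-integer input
in the gap maps to 3 points and logs a warning — fail-safe rather than
fail-hard on a measure-zero gap.

**Conservation.**  `conservation_count` maps a 1-based protein position
to its alignment column by counting non-gap reference residues, then
counts rows (reference included, so the minimum is 1) whose residue
equals the reference residue; gaps never count.  The published bins
assume an 8-species panel and `strict8` mode enforces that;
`proportional` mode extrapolates the bins as fractions (≥ 100 % → 5,
≥ 75 % → 4, ≥ 50 % → 3, else 1) for other panel sizes and logs that it
is extrapolating.  The 8-species count includes *Homo sapiens*: the
homolog panel the rubric was built on lists exactly eight species with
the human reference among them.

**Classification.**  Totals range over [2, 10].  The published bands
overlap at exactly 8 ("≥ 8 high" vs "6–8 moderate"); `ph1kit` gives
"high" precedence — the high band is stated first, and the only
exemplified scores are a 9 called high and a 6 called moderate — and
logs every boundary hit so the ambiguity is auditable.  Nonsense
variants are deliberately outside the rubric: a premature stop is a null
allele, reported as presumed deleterious.

## Phasing and segregation

**Model.**  *AGXT* spans ~10 kb, so intragenic recombination is
neglected: each individual's two gene copies are whole haplotypes
(subsets of the variant set) inherited intact.  The 74-bp intron-1
duplication (IVS1+74bp), though a polymorphic tag rather than a
mutation, is phased like any other marker; the AGT-Mi label attaches
post hoc to whichever haplotype carries it.

**Algorithm.**  Exact enumeration with pruning.  Founders' haplotype
pairs are enumerated subject to their own genotypes (a heterozygous
variant goes on one of the two haplotypes; untyped founders are
unconstrained over the observed variant set); each non-founder chooses
one haplotype from each parent; any assignment contradicting an observed
genotype is discarded immediately.  Two economies keep this exact search
small: individuals that are neither typed nor ancestral to a typed
individual cannot constrain phase and are excluded, and identical
parental haplotypes (e.g. two empty ones) are enumerated once.  The
search refuses inputs beyond 10 informative founders or 6 observed
variants and carries a 5-million-node budget so degenerate inputs fail
fast.

The cis/trans partition is read off the non-empty haplotypes carried by
*typed* individuals, so untransmitted haplotypes of untyped founders
cannot create spurious phase claims.  A unique surviving partition is
"resolved"; several are "ambiguous" (all listed); none is
"inconsistent".

**Segregation.**  Given a resolved phase, individuals are classified
from genotype alone: biallelic (mutant content from both haplotype
classes, or homozygous at any variant), carrier, noncarrier, or untyped —
the four counts always sum to the pedigree size.  The fully penetrant
autosomal-recessive model requires every affected individual biallelic
and no unaffected individual biallelic; `complete_penetrance=False`
downgrades the unaffected-biallelic rule to a warning, since reduced
penetrance is plausible while an affected non-carrier is a phenocopy
question the flag should not hide.

**Allele frequency** is the alt-allele count over twice the number of
typed individuals; missing genotypes leave the denominator.

## Clinical metrics

**MDRD eGFR.**  The 4-variable MDRD equation with the classic 186
coefficient: eGFR = 186 · (Scr/88.4)⁻¹·¹⁵⁴ · age⁻⁰·²⁰³, × 0.742 for
women, Scr in µmol/L, result in ml/min rounded to one decimal for
reporting (`precision=None` returns the raw value; properties such as
strict monotonicity in Scr and age are stated for the raw value).  The
classic variant was chosen over the IDMS-traceable 175 variant because
it reproduces the study patients' reported values far better (the 175
variant is ~6 % lower across the board); the remaining discrepancies on
two of the three patients are 0.16 % and 0.37 %.  The Black-ethnicity
factor is omitted as inapplicable to the cohort.

**OCR.**  The oxalate-to-creatinine ratio is dimensionless (mmol/mmol ≡
mol/mol) and stored unitless.  Abnormal means strictly above 0.04; 0.04
itself is normal.

**Pyridoxine response.**  Percent reduction 100·(before − after)/before;
responsive means strictly more than 30 %.  A 10⁻⁹ epsilon keeps an
exactly-30 % reduction non-responsive despite floating-point noise in
the subtraction.

**Diagnosis.**  The adult rule set: (nephrolithiasis OR
nephrocalcinosis) AND (abnormal OCR OR deficient hepatic AGT activity OR
biallelic pathogenic *AGXT* mutations).  Confirmatory fields are
tri-state; with the stone prong satisfied, any known-true confirmatory
item meets criteria, all-known-false fails them, and anything else is
`insufficient_data`.  "Recurrent urolithiasis" is operationalized as the
nephrolithiasis flag (no numeric recurrence threshold exists), and the
enzymology prong accepts only a boolean because the cited activity
ranges (2–48 % residual in 30–50 % of patients) state no actionable
cutoff.

## Synthetic data

All generators thread a single seeded `numpy` generator — identical spec
and seed give identical output — and plant *exact* quantities, not
expected ones, so recovery tests are sharp.

* **Pedigrees**: founders receive specified haplotype pairs; children
  inherit one whole haplotype from each parent uniformly at random;
  married-in spouses are wild type; the phenotype is assigned from
  genotype (biallelic ⇒ affected, fully penetrant).  Defaults (3
  generations, 3 offspring per couple) mirror the study family's scale.
* **Alignments**: 8 species by default; at planted columns exactly the
  requested number of rows (reference included) match the reference
  residue; elsewhere rows match with probability `background_identity`
  (default 0.7, typical of a vertebrate homolog panel), with accidental
  matches resampled.  Alignments are generated ungapped — gap handling
  in position mapping and conservation counting is exercised by
  hand-built gapped fixtures in the tests.
* **Cohorts**: exact heterozygote/homozygote counts per variant, shuffled
  under the seed; default size 100, the scale of a single-centre healthy
  control panel.

The 20-member study family is encoded directly in code
(`make_family_fixture`) rather than stored as a data file, so the
published genotype statements remain the single source of truth.  The
spousal/offspring wiring among unnamed members is an encoding choice
constrained to be Mendelian-consistent and phase-resolvable.

**What passing tests do and do not show.**  The generators emulate clean
Sanger-style genotype tables, complete phenotyping, exact conservation
counts and no recombination, genotyping error, or missingness beyond
what a test injects.  Passing recovery tests therefore validates the
*logic* (phase enumeration, rubric arithmetic, counting) — not
robustness to real-data artefacts such as miscalled genotypes,
misalignment, or reduced penetrance.

## Known limitations

* The phasing engine is exact but exponential; it is intended for
  single-gene, family-scale problems (its refusal limits), not
  population phasing — no EM/HMM, no LOD-score linkage.
* The variant parser covers the notation the package needs (protein and
  cDNA substitutions, simple duplications, paired forms), not the full
  HGVS grammar; intronic offsets are reduced to the IVS1+74bp tag.
* No transcript validation against a reference sequence: coordinates are
  checked only for internal codon consistency and against the supplied
  alignment's reference row.
* X-linked and mitochondrial inheritance models are out of scope.
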