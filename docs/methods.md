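# Methods

## The screening model

The pipeline classifies mtDNA substitutions and 1-bp deletions falling in
the 22 human mitochondrial tRNA genes into three tiers:

* **putative mutation** — evolutionarily conserved (CI strictly above the
  threshold, default 75%), absent from the control cohort (default
  policy), and predicted to alter tRNA structure or function;
* **rare conserved variant** — conserved, below the control-frequency
  cutoff but not absent (or conserved, absent, yet without predicted
  impact);
* **polymorphism** — not conserved, or at/above the control-frequency
  cutoff (default 1%).

The three tiers partition any input set.  Classification is monotone by
construction: lowering CI or raising the control carrier count can never
move a variant toward the putative tier.

### Conservation index

CI(p) = 100 × (non-human species matching the human base at p) /
(non-human species counted).  Matching is by exact character after
uppercasing and T/U unification.  Published CI values rarely state how
alignment gaps enter the denominator, so the counting mode is explicit:
`non_gap` (default) drops gapped species from the denominator;
`all_species` scores gaps as mismatches.  The exact rational is kept and
the strict `CI > threshold` comparison is made on it, not on the rounded
2-decimal percentage, so threshold-boundary values (e.g. exactly 12/16 =
75%) are classified deterministically.  When no alignment is supplied the
pipeline accepts precomputed per-variant CI values from the input table;
this is how the bundled dataset is screened, since the 16-species
alignments behind its published CI column are not distributed with it.

### Watson–Crick effect

Only A-U and G-C count as Watson–Crick; G·U wobble is non-WC.  This
convention is forced by the screening tables this pipeline reproduces,
which mark A→G opposite U as a pair loss.  A stem variant `disrupts_pair`
when the reference pair is WC and the alternate is not, `creates_pair` in
the converse case, and `no_pair_change` otherwise.  Deletions in a stem
count as disrupting when the reference pair was WC; deletions elsewhere
and all loop/junction/terminus positions are `not_applicable`.  Pairs are
reported as (variant-position base, partner base) on the tRNA strand —
published tables are not consistent about the orientation of the two
letters, so golden tests compare the unordered base set plus the
direction.

### Structural/functional impact (criterion 3)

Stem positions: impact iff the WC status changes.  Non-stem positions:
impact iff the position is conserved or belongs to the functional-site
list — by default conventional positions {8, 14, 18, 34, 37, 38, 55, 58,
73} (the 8–14 and 18–55 tertiary contacts, the wobble base 34 and
anticodon-adjacent 37/38, the T-loop 55/58 pair, the discriminator) plus
any position in the gene's tertiary-interaction list.  The site list is
overridable per call.

### Frequencies and prevalence

Control frequencies are exact rationals (`Fraction(carriers,
n_controls)`); "<1%" is strict, "≥1%" is common.  With 485 controls this
puts counts 1–4 in the rare class and 5+ in the common class.  Cohort
prevalence of the putative tier is the sum of per-variant case carrier
counts over the case count, assuming no subject carries two putative
variants; percentages are printed to 2 decimals from the exact value.

## The structural model

Gene definitions live in a human-editable text fixture
(`src/mttrna/data/structure.txt`): per gene, the rCRS span, strand, and an
ordered 5'→3' list of conventional positions with base, element, pairing
partner and optional tertiary contacts.  Conventional numbering is stored
as opaque labels with an integer sort key (insertions such as `27a` are
labels, not recomputed Sprinzl numbers).  Gene spans follow the standard
rCRS annotation with two deliberate 1–3 bp trims where the standard
annotation overlaps neighbouring genes (MT-TI 4263–4328 against MT-TQ;
MT-TY 5827–5891 against MT-TC), so that coordinate lookup is unambiguous;
no catalogued tRNA variant position falls in the trimmed bases.  The
light-strand gene set {MT-TQ, MT-TA, MT-TN, MT-TC, MT-TY, MT-TS1, MT-TE,
MT-TP} is data in the fixture, not logic.

Element layouts and numbering were chosen to reproduce the bundled cohort
table exactly: every one of its 73 rows maps to the printed conventional
position and structural location, and every printed pairing arrow is
reproduced after strand normalization.  Two quirks of that table are
followed or documented deliberately:

* its "ACC stem" label for MT-TT positions 39/42/43 (anticodon-stem 3'
  side by canonical numbering) is kept as the element assignment, while
  the pairing partners remain 31/28/27 so the printed arrows still follow;
* its tRNA-nucleotide number 98 for m.14693A>G is a printing error (no
  cloverleaf position 98 exists); the model places the position at 54,
  consistent with every other row of MT-TE, and the golden test asserts
  this exception explicitly.

Reference bases are pinned by the cohort table wherever it constrains them
(73 variant positions and 20+ pairing partners, with all cross-checks
between rows consistent); remaining stem bases are filled Watson–Crick and
remaining loop bases with a fixed deterministic pattern.  They are
**synthetic placeholders**, not the rCRS sequence — adequate for pairing
logic and rendering, not for sequence retrieval, and the fixture header
says so.

## Synthetic data

The generator's defaults are the study conditions of the bundled dataset:
494 cases, 485 controls, 73 variants in an 18/12/43 putative / rare
conserved / polymorphism mix (putative placement 7/9/2 across
loop/stem/terminal-junction classes), 16 aligned non-human species.
Variants are placed at real cloverleaf positions such that the tier is
determined by construction — putative stem variants start from a WC pair
(any alternate base then disrupts it), putative tiers get control count 0
and CI in (75, 100], polymorphism CI stays ≤ 75 so the tier is
count-independent — and a truth table is returned.  Screen-vs-truth
recovery is therefore an exact oracle test, not a statistical one.
Alignments are generated to hit requested CIs exactly (targets must be
multiples of 100/species); cohorts realize clinical rates exactly by
largest-remainder apportionment, or binomially in stochastic mode.  All
randomness flows from one `numpy` generator seeded explicitly; written
tables carry the seed in a provenance header.

What the generator does **not** emulate: sequencing error, haplogroup
structure, linkage between variants, per-subject genotypes (carrier counts
are marginal), or realistic site-frequency spectra.  Passing tests
therefore demonstrate correctness of the screening logic under its stated
assumptions, not calibration against real population data.

## Numerical and design choices

* Exact rationals for every threshold comparison; floats only at print
  time (2 decimals).
* Strict inequalities at both thresholds (CI = 75 is not conserved;
  control frequency exactly 1% is common).
* The `absent_only` policy is the default because the putative tier of the
  bundled dataset has control count 0 throughout; the broader
  "absent or <1%" reading is available as `--policy rare_allowed` rather
  than silently chosen.
* Deletions get no WC arrow in reports (`pair_text` empty) but still count
  as stem-disrupting when they remove a WC pair.
* Duplicate (position, ref, alt) records are input errors; positions
  outside 1..16569 are range errors; a position outside every tRNA span is
  a distinguished not-in-tRNA result, not a parse error.
* Reports are byte-deterministic: fixed column order, rows sorted by gene
  then position.

## Known limitations

* Fixture bases off the constrained positions are synthetic (above), so
  CI computed from a real alignment of the reference sequence would not
  match the fixture sequence at those positions.
* The per-gene cloverleaf layouts interpolate between the positions the
  cohort table constrains; unconstrained stretches follow canonical
  numbering and may differ from curated structural databases in detail.
* VCF ingestion is deliberately minimal (mitochondrial SNVs and 1-bp
  deletions; carrier counts from `CASES`/`CONTROLS` INFO keys).
* No statistical association testing is performed — the screen is a
  deterministic filter, and nothing here corrects for multiple testing.
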