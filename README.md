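# mttrna

Annotation and pathogenicity screening of human mitochondrial tRNA variants.

Point mutations in the 22 mt-tRNA genes are a recurrent cause of maternally
inherited disease, and candidate variants from cohort sequencing need a
reproducible triage: which of them plausibly damage the tRNA, and which are
ordinary population polymorphisms?  `mttrna` implements the screening
procedure used in clinical mt-tRNA surveys as a tested, reusable pipeline:

1. **Structural annotation.** Every rCRS (NC_012920.1) coordinate inside a
   tRNA gene is mapped to its conventional tRNA position (1–73, with
   insertion labels such as 27a) and cloverleaf element (acceptor stem,
   D-arm, anticodon arm, variable loop, T-arm, junctions, discriminator).
   Eight genes are light-strand encoded, so heavy-strand alleles are
   complemented to tRNA-level bases (T rendered as U).
2. **Conservation.** The conservation index (CI) of a position is the
   percentage of aligned non-human species whose nucleotide matches the
   human one, computed exactly from per-gene multi-species FASTA alignments
   (or taken as supplied values when a table already carries them).
3. **Watson–Crick effect.** For stem positions, the variant's effect on the
   WC pair with the partner position is classified as `disrupts_pair`,
   `creates_pair` or `no_pair_change`; G·U wobble counts as non-WC.
4. **Three-criterion screen.** A variant is a *putative mutation* when
   CI > 75%, it is absent from controls (default policy; a `rare_allowed`
   policy admits control frequency < 1%), and it is predicted to alter
   tRNA structure or function (a WC change in a stem, or a conserved /
   tertiary-interaction site elsewhere).  Conserved variants failing only
   the frequency criterion are *rare conserved variants*; the rest are
   *polymorphisms*.  All frequency comparisons are exact-rational.

The package bundles a complete example dataset: the 73 mt-tRNA variants
ascertained in a cohort of 494 children with tic disorders and 485 matched
controls, with published conservation values, carrier counts and novelty
flags, plus the cloverleaf definitions of all 22 genes.  A seeded synthetic
generator (`mttrna.synth`) produces variant tables with known tiers,
alignments with exact target CIs, and cohorts with exact clinical rates, so
every stage is testable offline.

## Worked example

```sh
$ mttrna screen --use-supplied-ci --out out/
screened 73 variants: 18 putative, 12 rare conserved, 43 polymorphisms
reports written to out
```

`out/summary.tsv` then contains the headline counts: of the 73 variants, 32
pass the conservation criterion, partitioning by control frequency into 18
absent, 12 rare (<1%) and 2 common; the 18 putative mutations split 7 loop /
9 stem / 2 terminal-junction, all 9 stem members disrupt a WC pair; their 25
case carriers give a prevalence of 25/494 = 5.06%; 24 variants are novel and
49 previously reported.  `out/per_variant.tsv` holds one row per variant,
e.g.

```
gene   position  variant    trna_position  element         wc_status      wc_pair  ci_percent  tier
MT-TA  5595      m.5595G>A  65             t_stem          disrupts_pair  C-G↓     100.0       putative_mutation
MT-TA  5601      m.5601C>T  59             t_loop          not_applicable          59.0        polymorphism
```

and `out/decisions.log` records each criterion decision per variant.
A text cloverleaf with highlighted positions:

```
$ mttrna render MT-TT --highlight 25
MT-TT  tRNA-Thr  (heavy strand, m.15888-15953)
  acceptor_stem     1:G 2:U 3:C 4:G 5:U 6:C 7:A 39:A 42:G 43:G 66:U ...
  d_stem            10:G 11:U 12:G 13:U 22:A 23:C 24:A [25:C]
  ...
```

Other subcommands: `annotate` (structural annotation only), `ci`
(per-position conservation from a FASTA alignment), `cohort` (clinical
summary tables), `synth` (seeded synthetic variant tables with truth
tiers).  The same functionality is available as a library; see
`mttrna.screen`, `mttrna.annotate`, `mttrna.conservation_index`.

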