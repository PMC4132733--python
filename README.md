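# trnamass

Mass-spectrometric fragment assignment and modification-pathway logic for
modified tRNAs:

- **chem registry** — canonical and modified ribonucleosides stored as
  molecular formulas; monoisotopic/average masses are always derived from
  one element table (`trnamass.registry`, `trnamass.elements`).
- **sequence model** — bracket-notation modified sequences
  (`"U[t6A]AGp"`), tRNA records with standard numbering, point variants,
  bracket-FASTA I/O (`trnamass.sequence`).
- **digestion** — in-silico RNase T1 / RNase A digestion with missed
  cleavages, linear or 2',3'-cyclic phosphate products, and 2'-O-methyl
  blocking (`trnamass.digestion`).
- **mass calc** — fragment neutral masses, negative/positive ESI m/z,
  nucleoside [M+H]+ adducts at unit or accurate resolution, and c/y/w/a-B
  CID ladders (`trnamass.masscalc`).
- **matcher / screen** — ppm-tolerance peak assignment, deletion-strain
  differential screening with two-stage gene narrowing, normalized signal
  ratios and position-state stoichiometry (`trnamass.matching`).
- **pathway rules** — anticodon-arm determinant checks (U36, C31-G39,
  G34, G35) and genotype-driven prediction of the position-37 state
  (A / t6A / ct6A / m6t6A) (`trnamass.pathway`).
- **synthetic data** — seeded generators for modified tRNA records, noisy
  digest peak lists with truth tables, knockout panels with causal maps,
  and state mixtures (`trnamass.simulate`).

## CLI

```sh
trnamass mass "U[t6A]AGp"                 # neutral monoisotopic mass
trnamass mz 1472.2258 --charge 2 --neg    # m/z of the 2- ion
trnamass adduct m6t6A                     # unit-resolution [M+H]+
trnamass digest records.fasta --enzyme t1 --missed 1 --out fragments.tsv
trnamass match records.fasta peaks.csv --tol-ppm 10
trnamass screen panel.csv --reference WT
trnamass predict records.fasta --genotype trmO=0,tcdA=1
trnamass simulate --seed 7 --out-dir simulated/
```

Bracket-FASTA headers are `>id|organism|anticodon_start` where
`anticodon_start` is the 1-based index of standard position 34; sequence
lines use the bracket grammar (`[m6t6A]`, `[Y]` = pseudouridine, trailing
`p` = 3'-phosphate, `>p` = cyclic).

Exit codes: 0 success, 1 bad input data, 2 bad arguments.

## Extending the registry

User residues can be added via a YAML file merged over the built-ins:

```yaml
residues:
  - code: x6A
    parent: A
    formula: C12H17N5O4
    base_class: purine
```

Redefining a built-in requires `override: true` on the entry. Pass the
file with `--registry` on the CLI or `load_registry(path)` in code.
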