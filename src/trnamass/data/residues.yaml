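# Built-in ribonucleoside registry.
#
# Each entry describes the FREE NUCLEOSIDE (base + ribose). Masses are never
# written here: they are derived from the formula over the element table.
#
# flags:
#   t1_cleavable      RNase T1 cleaves 3' of this residue
#   rnaseA_cleavable  RNase A cleaves 3' of this residue
#   ribose_2prime_methyl  2'-O-methylated ribose (blocks transesterification)
#
# Cleavability of m7G and m22G by RNase T1 is not established for the
# conditions modelled here; both default to non-cleavable and can be
# overridden through a user registry file.
residues:
  - code: A
    name: adenosine
    formula: C10H13N5O4
    base_class: purine
  - code: C
    name: cytidine
    formula: C9H13N3O5
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: G
    name: guanosine
    formula: C10H13N5O5
    base_class: purine
    t1_cleavable: true
  - code: U
    name: uridine
    formula: C9H12N2O6
    base_class: pyrimidine
    rnaseA_cleavable: true

  # --- pyrimidine modifications -------------------------------------------
  - code: Y
    name: pseudouridine
    aliases: ["Ψ", "psi", "psU"]
    parent: U
    formula: C9H12N2O6          # mass-silent isomer of uridine
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: D
    name: dihydrouridine
    parent: U
    formula: C9H14N2O6
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: m5U
    name: 5-methyluridine
    aliases: ["T", "rT"]
    parent: U
    formula: C10H14N2O6
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: Um
    name: 2'-O-methyluridine
    parent: U
    formula: C10H14N2O6
    base_class: pyrimidine
    ribose_2prime_methyl: true
  - code: m5C
    name: 5-methylcytidine
    parent: C
    formula: C10H15N3O5
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: m3C
    name: 3-methylcytidine
    parent: C
    formula: C10H15N3O5
    base_class: pyrimidine
    rnaseA_cleavable: true
  - code: Cm
    name: 2'-O-methylcytidine
    parent: C
    formula: C10H15N3O5
    base_class: pyrimidine
    ribose_2prime_methyl: true
  - code: ac4C
    name: N4-acetylcytidine
    parent: C
    formula: C11H15N3O6
    base_class: pyrimidine
    rnaseA_cleavable: true

  # --- purine modifications -----------------------------------------------
  - code: m1A
    name: 1-methyladenosine
    parent: A
    formula: C11H15N5O4
    base_class: purine
  - code: m2A
    name: 2-methyladenosine
    parent: A
    formula: C11H15N5O4
    base_class: purine
  - code: m6A
    name: N6-methyladenosine
    parent: A
    formula: C11H15N5O4
    base_class: purine
  - code: Am
    name: 2'-O-methyladenosine
    parent: A
    formula: C11H15N5O4
    base_class: purine
    ribose_2prime_methyl: true
  - code: m7G
    name: 7-methylguanosine
    parent: G
    formula: C11H15N5O5
    base_class: purine
  - code: m2G
    name: N2-methylguanosine
    parent: G
    formula: C11H15N5O5
    base_class: purine
  - code: m22G
    name: N2,N2-dimethylguanosine
    aliases: ["m2,2G", "m2_2G"]
    parent: G
    formula: C12H17N5O5
    base_class: purine
  - code: Gm
    name: 2'-O-methylguanosine
    parent: G
    formula: C11H15N5O5
    base_class: purine
    ribose_2prime_methyl: true

  # --- position-37 threonylcarbamoyl family -------------------------------
  - code: t6A
    name: N6-threonylcarbamoyladenosine
    parent: A
    formula: C15H20N6O8
    base_class: purine
  - code: m6t6A
    name: N6-methyl-N6-threonylcarbamoyladenosine
    parent: t6A
    formula: C16H22N6O8
    base_class: purine
  - code: ct6A
    name: cyclic N6-threonylcarbamoyladenosine
    parent: t6A
    formula: C15H18N6O7
    base_class: purine
  - code: ms2t6A
    name: 2-methylthio-N6-threonylcarbamoyladenosine
    parent: t6A
    formula: C16H22N6O8S
    base_class: purine
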