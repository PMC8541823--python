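# Rescue cross: elav-Gal4; CG31030[MI107]/TM6B females
#            x  w; UAS-CG31030/CyO; Df(3R)Exel6214/TM6B males.
# Mothers are homozygous for the X-linked driver, so every progeny carries it
# and the rescue condition reduces to presence of the UAS effector.
name: CG31030 deficiency rescue cross
chromosomes:
  X:
    mother: [elav-Gal4, elav-Gal4]
    father: [w, Y]
  "2":
    mother: ["+", "+"]
    father: [UAS-CG31030, CyO]
  "3":
    mother: [MI107, TM6B]
    father: [Df, TM6B]
lethal:
  - predicate: {chromosome: "3", homozygous: TM6B}
  - predicate: {chromosome: "3", genotype: [MI107, Df]}
    unless: {carries: UAS-CG31030}
classes:
  - label: heterozygous deficiency without CG31030 expression
    where:
      all:
        - any:
            - {chromosome: "3", genotype: [MI107, TM6B]}
            - {chromosome: "3", genotype: [Df, TM6B]}
        - not: {carries: UAS-CG31030}
  - label: heterozygous deficiency with pan-neuronal CG31030 expression
    where:
      all:
        - any:
            - {chromosome: "3", genotype: [MI107, TM6B]}
            - {chromosome: "3", genotype: [Df, TM6B]}
        - {carries: UAS-CG31030}
  - label: homozygous deficiency without CG31030 expression
    where:
      all:
        - {chromosome: "3", genotype: [MI107, Df]}
        - not: {carries: UAS-CG31030}
  - label: homozygous deficiency with pan-neuronal CG31030 expression
    where:
      all:
        - {chromosome: "3", genotype: [MI107, Df]}
        - {carries: UAS-CG31030}
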