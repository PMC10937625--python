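# Functional groups appended to extracted reaction templates when they touch
# the reaction center.  Names are reported in ReactionTemplate.extension_groups.
# Each entry lists one or more SMARTS patterns.
carbonyl:
  - "[CX3]=[OX1]"
carboxylic_acid:
  - "[CX3](=[OX1])[OX2H1]"
ester:
  - "[CX3](=[OX1])[OX2H0][#6]"
amide:
  - "[CX3](=[OX1])[NX3]"
nitrile:
  - "[NX1]#[CX2]"
nitro:
  - "[NX3+](=[OX1])[OX1-]"
  - "[NX3](=[OX1])=[OX1]"
acetal:
  - "[CX4]([OX2])([OX2])"
imine:
  - "[CX3]=[NX2]"
sulfonyl:
  - "[SX4](=[OX1])(=[OX1])"
boronic:
  - "[BX3]([OX2])[OX2]"
organohalide:
  - "[#6][F,Cl,Br,I]"
aromatic_heteroatom:
  - "[a;!#6]"
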