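# ACMG/AMP evidence-combining rules (Richards et al. 2015 five-tier scheme),
# restricted to the evidence-strength categories this package can populate.
# Each rule is a minimum-count requirement over strength categories:
#   PVS = pathogenic very strong, PS = pathogenic strong,
#   PM = pathogenic moderate, PP = pathogenic supporting,
#   BA = benign stand-alone, BS = benign strong, BP = benign supporting.
# A verdict fires when any one of its rules is satisfied. Pathogenic rules
# are checked before Likely pathogenic; Benign before Likely benign.
version: 1
pathogenic:
  - {PVS: 1, PS: 1}
  - {PVS: 1, PM: 2}
  - {PVS: 1, PM: 1, PP: 1}
  - {PVS: 1, PP: 2}
  - {PS: 2}
  - {PS: 1, PM: 3}
  - {PS: 1, PM: 2, PP: 2}
  - {PS: 1, PM: 1, PP: 4}
likely_pathogenic:
  - {PVS: 1, PM: 1}
  - {PS: 1, PM: 1}
  - {PS: 1, PP: 2}
  - {PM: 3}
  - {PM: 2, PP: 2}
  - {PM: 1, PP: 4}
benign:
  - {BA: 1}
  - {BS: 2}
likely_benign:
  - {BS: 1, BP: 1}
  - {BP: 2}
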