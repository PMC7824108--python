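# Targeted LPA/PA sixplex panel (the printed duplicate PA(36:2) is
# deduplicated at build time with a warning).
panel:
  - LPA(16:0)
  - LPA(18:0)
  - LPA(18:1)
  - LPA(18:2)
  - LPA(20:4)
  - PA(32:0)
  - PA(34:1)
  - PA(34:2)
  - PA(36:0)
  - PA(36:2)
  - PA(36:3)
  - PA(36:2)
  - PA(36:4)
  - PA(38:4)
channels:
  bridge: "131"
acquisition:
  ce: 46
rule_mode: paper_nominal
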