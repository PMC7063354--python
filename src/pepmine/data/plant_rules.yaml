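# Plant cysteine proteases: papain, ficin, stem bromelain.
# Best-effort Keil/PeptideCutter-style provisional site models; the exact
# encodings used by online digestion tools are unpublished. Edit freely.
enzymes:
  - enzyme_id: papain
    ec_number: 3.4.22.2
    sites:
      - p2: AVLIFWY
        p1: "*"
        blocked:
          - position: p1_prime
            residues: V
      - p1: RK
        blocked:
          - position: p1_prime
            residues: V
  - enzyme_id: ficin
    ec_number: 3.4.22.3
    sites:
      - p2: FYWLVI
        p1: "*"
  - enzyme_id: stem_bromelain
    ec_number: 3.4.22.32
    sites:
      - p1: KRAYG
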