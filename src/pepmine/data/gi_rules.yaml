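# Gastrointestinal digestion rule set: pepsin (pH > 2.0), trypsin,
# chymotrypsin A. Calibrated so the engine reproduces the published
# worked examples of simulated tripeptide digestion; editable config,
# not an authoritative reconstruction of any external tool's models.
enzymes:
  - enzyme_id: pepsin_ph_gt2
    ec_number: 3.4.23.1
    sites:
      - p1: FLWY
      - p1: "*"
        p1_prime: FLWYM
        blocked:
          - position: p1
            residues: P
  - enzyme_id: trypsin
    ec_number: 3.4.21.4
    sites:
      - p1: KR
        blocked:
          - position: p1_prime
            residues: P
  - enzyme_id: chymotrypsin_a
    ec_number: 3.4.21.1
    sites:
      - p1: FYWLMH
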