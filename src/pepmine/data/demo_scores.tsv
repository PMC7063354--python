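peptide	ranker_score	toxicity
MAF	0.9676	Non-Toxin
NMF	0.9624	Non-Toxin
HPF	0.9502	Non-Toxin
MCG	0.9502	Non-Toxin
WCY	0.9816
CG	0.9319
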