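# The 19 sequenced non-mutator clones of the long-term E. coli evolution
# experiment. Clones carrying no synonymous substitution (all of Ara-1,
# and Ara+2 clone 40K-B) still contribute informative Poisson zeros to
# rate estimation.
population	clone	generation
Ara-1	20K-A	20000
Ara-1	20K-B	20000
Ara-1	20K-C	20000
Ara-3	30K-A	30000
Ara-3	30K-B	30000
Ara-3	40K	40000
Ara-5	40K-A	40000
Ara-5	40K-B	40000
Ara-5	40K-C	40000
Ara-6	40K-A	40000
Ara-6	40K-B	40000
Ara+1	40K-A	40000
Ara+1	40K-B	40000
Ara+2	40K-A	40000
Ara+2	40K-B	40000
Ara+4	40K-A	40000
Ara+4	40K-B	40000
Ara+5	40K-A	40000
Ara+5	40K-B	40000
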