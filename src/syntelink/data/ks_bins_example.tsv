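# Illustrative (non-canonical) Ks intervals mapping recent-to-ancient plant
# polyploidy events; Ks bin boundaries are study-specific and should be set
# from the Ks distribution of the genomes at hand.
# Columns: label, lo, hi, age_mya (half-open interval [lo, hi)).
alpha-like	0.0	0.9	50
beta-like	0.9	1.6	75
lambda-like	1.6	3.0	150
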