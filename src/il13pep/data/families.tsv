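# Descriptor-family manifest for the 9151-dimensional composition feature
# space. Families are encoded in this order; dims are validated against the
# generated feature names at catalog load time and must sum to 9151.
family	dim	description
AAC	20	amino-acid composition (%)
DPC	400	dipeptide composition over overlapping 2-mers (%)
TPC	8000	tripeptide composition over overlapping 3-mers (%)
ATC	5	atom-type composition over C/H/N/O/S atoms (%)
BTC	4	bond composition: total, hydrogen, single, double bond counts
PCP	30	physicochemical-property class composition (%)
SER	20	per-residue-type Shannon entropy (bits)
SE	1	whole-sequence Shannon entropy (bits)
RRI	20	residue-repeat information per residue type
DDR	20	distance distribution of residue occurrences per residue type
CTC	343	conjoint-triad composition over 7 residue classes (%)
CeTD	288	composition/transition/distribution over 8 physicochemical attributes
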