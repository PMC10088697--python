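# Three-group partitions of the 20 amino acids under 8 physicochemical
# attributes, used by the composition/transition/distribution (CeTD) family.
# HB/VW/PO/PZ/CH/SS/SA follow the Dubchak-standard groupings used by common
# CTD implementations (hydrophobicity, normalized van der Waals volume,
# polarity, polarizability, charge, secondary-structure propensity, solvent
# accessibility). FL is a three-way split of the Vihinen flexibility scale
# (rigid / intermediate / flexible) adopted by this package.
attribute	group	residues
HB	1	RKEDQN
HB	2	GASTPHY
HB	3	CLVIMFW
VW	1	GASCTPD
VW	2	NVEQIL
VW	3	MHKFRYW
PO	1	LIFWCMVY
PO	2	PATGS
PO	3	HQRKNED
PZ	1	GASDT
PZ	2	CPNVEQIL
PZ	3	KMHFRYW
CH	1	KR
CH	2	ANCQGHILMFPSTWYV
CH	3	DE
SS	1	EALMQKRH
SS	2	VIYCWFT
SS	3	GNPSD
SA	1	ALFCGIVW
SA	2	RKQEND
SA	3	MPSTHY
FL	1	WCFIYVL
FL	2	HMATRGQ
FL	3	SNPDEK
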