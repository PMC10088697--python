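# Physicochemical-property residue classes for the PCP composition family.
# Each feature is the percentage of residues belonging to the class.
# Memberships follow common usage (Taylor-style classes, Kyte-Doolittle
# hydropathy, Chou-Fasman secondary-structure preference, burial statistics).
code	residues	description
PCP_PC	KRH	positively charged
PCP_NC	DE	negatively charged
PCP_NE	ACFGILMNPQSTVWY	charge-neutral
PCP_PO	DEHKNQRSTY	polar
PCP_NP	ACFGILMPVW	nonpolar
PCP_AL	AGILV	aliphatic
PCP_AR	FHWY	aromatic
PCP_CY	FHPWY	cyclic
PCP_AC	DE	acidic
PCP_BS	HKR	basic
PCP_HBC	ACFILMV	hydrophobic (positive hydropathy)
PCP_HLC	DEHKNQR	hydrophilic
PCP_TN	ACGS	tiny
PCP_SM	ACDGNPSTV	small
PCP_LR	FHIKLMRWY	large
PCP_SS_HE	AEHKLMQR	helix-preferring
PCP_SS_ST	CFITVWY	strand-preferring
PCP_SS_CO	DGNPS	coil-preferring
PCP_SA_BU	ACFGILVW	preferentially buried
PCP_SA_EX	DEKNPQR	preferentially exposed
PCP_SA_IN	HMSTY	intermediate burial
PCP_SF	CM	sulfur-containing
PCP_HX	STY	hydroxylic
PCP_AM	NQ	amidic
PCP_HBD	CHKNQRSTWY	side-chain H-bond donor
PCP_HBA	DEHNQSTY	side-chain H-bond acceptor
PCP_BR	ILTV	beta-branched or branched-chain
PCP_CHG	DEHKR	charged
PCP_FLX	DEGKNPQS	flexible (high mobility)
PCP_RIG	CFILVWY	rigid (low mobility)
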