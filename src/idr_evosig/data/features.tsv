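# Canonical 82-entry molecular-feature registry for disordered-region analysis.
# Columns: name, kind, spec, note.  kinds: composition_fraction (spec = residue
# class), repeat (spec = residue class, counts runs >= 2), regex_count (spec =
# regular expression, non-overlapping counts), physicochemical / patterning /
# length_derived (spec = builtin function name or exponent).
# Provenance: the in-text anchors of the feature set (fraction_S, repeat_QN,
# repeat_K, net_charge, isopoint, hydrophobicity, disorder_fraction,
# wf_complexity, SCD, kappa, omega, PPII, the glycine-free polar class
# [QNSTCH], the excluded-volume Rg length proxy, and ELM DOC/LIG/MOD motif
# classes) fix 40+ entries; the remaining entries are reconstructed from
# canonical published definitions (per-residue compositions and repeats, ELM
# consensus regexes).  Deviations from any original spreadsheet are therefore
# possible and each entry's note states what it computes.
name	kind	spec	note
fraction_A	composition_fraction	A	single-residue composition fraction
fraction_C	composition_fraction	C	single-residue composition fraction
fraction_D	composition_fraction	D	single-residue composition fraction
fraction_E	composition_fraction	E	single-residue composition fraction
fraction_F	composition_fraction	F	single-residue composition fraction
fraction_G	composition_fraction	G	single-residue composition fraction
fraction_H	composition_fraction	H	single-residue composition fraction
fraction_I	composition_fraction	I	single-residue composition fraction
fraction_K	composition_fraction	K	single-residue composition fraction
fraction_L	composition_fraction	L	single-residue composition fraction
fraction_M	composition_fraction	M	single-residue composition fraction
fraction_N	composition_fraction	N	single-residue composition fraction
fraction_P	composition_fraction	P	single-residue composition fraction
fraction_Q	composition_fraction	Q	single-residue composition fraction
fraction_R	composition_fraction	R	single-residue composition fraction
fraction_S	composition_fraction	S	single-residue composition fraction
fraction_T	composition_fraction	T	single-residue composition fraction
fraction_V	composition_fraction	V	single-residue composition fraction
fraction_W	composition_fraction	W	single-residue composition fraction
fraction_Y	composition_fraction	Y	single-residue composition fraction
fraction_polar	composition_fraction	QNSTCH	polar residue fraction; class excludes glycine
fraction_aromatic	composition_fraction	FWY	aromatic residue fraction
fraction_aliphatic	composition_fraction	AVLIM	aliphatic/hydrophobic residue fraction
fraction_charged	composition_fraction	DEKR	charged residue fraction (His neutral)
fraction_positive	composition_fraction	KR	basic residue fraction
fraction_negative	composition_fraction	DE	acidic residue fraction
repeat_A	repeat	A	count of runs of >=2 consecutive A
repeat_C	repeat	C	count of runs of >=2 consecutive C
repeat_D	repeat	D	count of runs of >=2 consecutive D
repeat_E	repeat	E	count of runs of >=2 consecutive E
repeat_F	repeat	F	count of runs of >=2 consecutive F
repeat_G	repeat	G	count of runs of >=2 consecutive G
repeat_H	repeat	H	count of runs of >=2 consecutive H
repeat_I	repeat	I	count of runs of >=2 consecutive I
repeat_K	repeat	K	count of runs of >=2 consecutive K
repeat_L	repeat	L	count of runs of >=2 consecutive L
repeat_M	repeat	M	count of runs of >=2 consecutive M
repeat_N	repeat	N	count of runs of >=2 consecutive N
repeat_P	repeat	P	count of runs of >=2 consecutive P
repeat_Q	repeat	Q	count of runs of >=2 consecutive Q
repeat_R	repeat	R	count of runs of >=2 consecutive R
repeat_S	repeat	S	count of runs of >=2 consecutive S
repeat_T	repeat	T	count of runs of >=2 consecutive T
repeat_V	repeat	V	count of runs of >=2 consecutive V
repeat_W	repeat	W	count of runs of >=2 consecutive W
repeat_Y	repeat	Y	count of runs of >=2 consecutive Y
repeat_QN	repeat	QN	count of runs of >=2 consecutive Q/N residues
hydrophobicity	physicochemical	hydropathy	mean Kyte-Doolittle hydropathy
isopoint	physicochemical	isoelectric_point	isoelectric point, bisection on Henderson-Hasselbalch net charge, EMBOSS pKa table
net_charge	physicochemical	net_charge	count(K,R) - count(D,E); His neutral
ncpr	physicochemical	ncpr	net charge per residue
ppii_propensity	physicochemical	ppii_propensity	mean polyproline-II propensity (Elam/Hilser scale)
wf_complexity	physicochemical	wf_complexity	Wootton-Federhen K1 complexity, base-20 logarithm
scd	patterning	scd	sequence charge decoration: (1/N) sum_{i<j} q_i q_j sqrt(j-i)
kappa	patterning	kappa	Das-Pappu charge patterning, blobs 5 and 6, normalized by segregated-arrangement maximum
omega	patterning	omega	Das-Pappu patterning of {D,E,K,R,P} vs other residues
rg_scaling	length_derived	0.598	N**0.598, radius-of-gyration proxy for an excluded-volume polymer
disorder_fraction	physicochemical	disorder_fraction	fraction of residues with disorder score >= 0.5; missing when no scores attached
MOD_CDK_SPxK	regex_count	[ST]P.[KR]	CDK phosphorylation site; non-overlapping match count, not normalized
MOD_PKA	regex_count	RR.[ST]	PKA phosphorylation site; non-overlapping match count, not normalized
MOD_CK1	regex_count	S..[ST]	CK1 phosphorylation site; non-overlapping match count, not normalized
MOD_CK2	regex_count	[ST]..[ED]	CK2 phosphorylation site; non-overlapping match count, not normalized
MOD_GSK3	regex_count	[ST]...[ST]	GSK3 phosphorylation site; non-overlapping match count, not normalized
MOD_SUMO	regex_count	[VILMAFP]K.E	sumoylation consensus; non-overlapping match count, not normalized
MOD_PIKK	regex_count	[ST]Q	PIKK family phosphorylation site; non-overlapping match count, not normalized
MOD_PLK	regex_count	[DE].[ST][VILMAF]	Polo-like kinase site; non-overlapping match count, not normalized
MOD_ProDKin	regex_count	[ST]P	proline-directed kinase site; non-overlapping match count, not normalized
MOD_N_GLC	regex_count	N[^P][ST]	N-glycosylation sequon; non-overlapping match count, not normalized
DOC_MAPK_D	regex_count	[KR]{2,3}.{2,4}[LIVP].[LIV]	MAPK docking D-motif; non-overlapping match count, not normalized
DOC_CYCLIN_RxL	regex_count	[RK].L.?[FYLIVMP]	cyclin docking motif; non-overlapping match count, not normalized
DOC_PP1_RVxF	regex_count	[RK].[VI].[FW]	PP1 docking motif; non-overlapping match count, not normalized
DOC_PP2B_PxIxI	regex_count	P.I.I	calcineurin docking motif; non-overlapping match count, not normalized
DOC_USP7_MATH	regex_count	[PA][^P][^FYWIL]S[^P]	USP7 MATH-domain docking motif; non-overlapping match count, not normalized
DOC_PP4_FxxP	regex_count	F..P	PP4 docking motif; non-overlapping match count, not normalized
LIG_SH3_1	regex_count	[RKY]..P..P	SH3 class I ligand; non-overlapping match count, not normalized
LIG_SH3_2	regex_count	P..P.[KR]	SH3 class II ligand; non-overlapping match count, not normalized
LIG_SH2_GRB2	regex_count	Y.N	GRB2 SH2 ligand; non-overlapping match count, not normalized
LIG_PDZ_1	regex_count	[ST].[VIL]$	class I PDZ-binding C-terminus; non-overlapping match count, not normalized
LIG_14_3_3	regex_count	R..[ST].P	14-3-3 binding phosphomotif; non-overlapping match count, not normalized
LIG_WW_1	regex_count	PP.Y	WW domain PPxY ligand; non-overlapping match count, not normalized
LIG_EH_NPF	regex_count	.NPF.	EH domain NPF ligand; non-overlapping match count, not normalized
LIG_TRAF2	regex_count	[PSAT].QE	TRAF2 binding motif; non-overlapping match count, not normalized
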