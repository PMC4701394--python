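name	exon1	ss5	bs	u1_overrides	u2_overrides	observed_class	efficiency	source
res1'	AAG	GUUUGU	CUAAC			DEPENDENT	NORMAL	Fig 3C; reporter wild type, RSEI -1.36
res1'-1	NAG	GUAAGU	CUAAC	-3:WC		INDEPENDENT	NORMAL	Fig 3D; -3/+3/+4 mutated (-3 identity shown only as pair state)
res1'-2	AAG	GUAAGU	CUAAC			INDEPENDENT	NORMAL	Fig 3D; +3/+4 mutated
res1'-3	AAG	GUAUGU	CUAAC			INDEPENDENT	NORMAL	Fig 3E; +3 contact only, efficient at all time points
res1'-4	AAG	GUUAGU	CUAAC			INDEPENDENT	REDUCED	Fig 3E; +4 psi-A contact only, slightly reduced after inhibition
res1'-5	AAG	GUAAAU	CUAAC			DEPENDENT	NORMAL	Fig 3F; +5 G-to-A on the strong 5'SS
res1'-6	AAG	CUUUGU	CUAAC			NOT_RECOGNIZED	SEVERE	Fig 3G; +1 G-to-C control
res1'-7	AAG	GUAAGN	CUAAC	+6:NONE		INDEPENDENT	NORMAL	Fig 3G; +6 non-pairing on the strong 5'SS
res1'-8	AAG	GUUUGN	CUAAC	+6:NONE		NOT_RECOGNIZED	SEVERE	Fig 3H; no contacts at +3, +4 and +6
res1'-10	NNG	GUAAGU	CUAAC	-3:NONE,-2:NONE		INDEPENDENT	REDUCED	Fig 3I; exon WC only at -1 (mutated identities shown as pair states)
res1'-11	NAN	GUAAGU	CUAAC	-3:NONE,-1:NONE		INDEPENDENT	REDUCED	Fig 3I; exon WC only at -2
res1'-12	CNN	GUAAGU	CUAAC	-2:NONE,-1:NONE		DEPENDENT	NORMAL	Fig 3I; exon WC only at -3
res1'-13	NNN	GUAAGU	CUAAC	-3:NONE,-2:NONE,-1:NONE		DEPENDENT	NORMAL	Fig 3I; no exon contacts
res1'-14	AAG	GAUUGU	CUAAC			NOT_RECOGNIZED	SEVERE	S2 Fig; +2 U-to-A control
res1'-15	AAG	GUAANU	CUAAC	+5:NONE		DEPENDENT	NORMAL	S2 Fig; +5 non-WC substitution
res1'-16	AAG	GUAANU	CUAAC	+5:NONE		DEPENDENT	NORMAL	S2 Fig; +5 non-WC substitution
res1'-17	AAG	GUAAGN	CUAAC	+6:NONE		INDEPENDENT	NORMAL	S2 Fig; +6 non-pairing substitution
res1'-18	AAG	GUAAGN	CUAAC	+6:NONE		INDEPENDENT	NORMAL	S2 Fig; +6 non-pairing substitution
ppk8'	NNG	GUAUGU		-3:NONE,-2:NONE		INDEPENDENT	NORMAL	Fig 4B/C; exon WC at -1 only (exon -2/-3 shown as pair states)
ppk8'-1	NNG	CUAUGU		-3:NONE,-2:NONE		NOT_RECOGNIZED	SEVERE	Fig 4C; +1 G-to-C
ppk8'-2	NNG	GUUAGU		-3:NONE,-2:NONE		DEPENDENT	NORMAL	Fig 4D; +3 A-to-U with +4 U-to-A (psi-A)
ppk8'-3	NNG	GUUUGU		-3:NONE,-2:NONE		NOT_RECOGNIZED	SEVERE	Fig 4D; contacts at +3 and +4 both absent
ppk8'-4	AAG	GUUUGU				DEPENDENT	NORMAL	Fig 4E; res1 exon1/5'SS transplanted
ppk8'-5	NNN	GUAUGU		-3:NONE,-2:NONE,-1:NONE		DEPENDENT	NORMAL	Fig 4F; no exon contacts
ppk8'-6	NNN	GUAUGU		-3:WC,-2:NONE,-1:NONE		DEPENDENT	NORMAL	Fig 4F; exon WC only at -3
ppk8'-7	NNN	GUAUGU		-3:NONE,-2:WC,-1:NONE		INDEPENDENT	NORMAL	Fig 4F; exon WC at -2
ppk8'-8	NNN	GUAUGU		-3:NONE,-2:NONE,-1:WC		INDEPENDENT	NORMAL	Fig 4F; exon WC at -1
res1'-A	AAG	GUUUGU	CUAUC			NOT_RECOGNIZED	SEVERE	Fig 5B; branch point A-to-U on the weak 5'SS
res1'-2A	AAG	GUAAGU	CUAUC			DEPENDENT	SEVERE	Fig 5B; branch point A-to-U on the strong 5'SS, trace mRNA only
res1'-B	AAG	GUUUGU	CUUAC			DEPENDENT	SEVERE	Fig 5C; bs position 3 A-to-U on the weak 5'SS
res1'-2B	AAG	GUAAGU	CUUAC			DEPENDENT	NORMAL	Fig 5C; bs position 3 A-to-U converts the strong 5'SS to dependent
res1'-C	AAG	GUUUGU	CGAAC			NOT_RECOGNIZED	SEVERE	Fig 5D; invariant bs position 2 U-to-G
res1'-2C	AAG	GUAAGU	CGAAC			NOT_RECOGNIZED	SEVERE	Fig 5D; invariant bs position 2 U-to-G
res1'-D	AAG	GUUUGU	NUAAC		1:NONE	DEPENDENT	SEVERE	Fig 5E; bs position 1 unpaired (identity shown as pair state)
res1'-2D	AAG	GUAAGU	NUAAC		1:NONE	INDEPENDENT	REDUCED	Fig 5E; bs position 1 unpaired on the strong 5'SS
res1'-E	AAG	GUUUGU	CUAAN		5:NONE	DEPENDENT	SEVERE	Fig 5F; bs position 5 unpaired
res1'-2E	AAG	GUAAGU	CUAAN		5:NONE	INDEPENDENT	REDUCED	Fig 5F; bs position 5 unpaired on the strong 5'SS
mrp17-I	CCA	GUAAGU				DEPENDENT	NORMAL	Fig 2D / Discussion; exon WC only at -3
mrp17-II	UAA	GUAUGU				INDEPENDENT	NORMAL	Fig 2D / Discussion; exon WC at -2 plus wobble at -3
ura4-res1	NNN	GUUUGU	CUAAC	-3:NONE,-2:WC,-1:WC		DEPENDENT	NORMAL	S3 Fig; synthetic pattern-based exon context (recognized intron implies intact exon pairing)
ura4-ade2-II	NNN	GUNNNN		-3:NONE,-2:WC,-1:WC,+3:WC,+4:PSI_STABLE,+5:WC,+6:WC		INDEPENDENT	NORMAL	S3 Fig; synthetic pattern-based register (sequences not printed)
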