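name	chrom	pos	kind	repeat_unit	ref_repeat_count
STR1	chr15	27922681	STR	GT	21
STR2	chr15	27954117	STR	CA	19
STRA	chr15	27965962	STR	GTTT	12
STRB	chr15	27972828	STR	ATTTT	9
rs1800407	chr15	27985172	SNP		
STR5	chr15	28009685	STR	CA	20
STR6	chr15	28042644	STR	TAAA	11
STR8	chr15	28074004	STR	CA	16
rs12913832	chr15	28120472	SNP		
STR9	chr15	28245567	STR	CA	18
STR10	chr15	28279616	STR	CA	17
rs12203592	chr6	396321	SNP		
rs16891982	chr5	33951588	SNP		
rs1393350	chr11	89277878	SNP		
rs12896399	chr14	92773663	SNP		
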