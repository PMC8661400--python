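gap_id	gap_bp	replaced_region	replaced_bp	gcs_source	gcs_bp
Chr1_gap2	9813	end of LOC409701 to start of LOC113218996	106010	ASM1384124v1	105996
Chr1_gap4	1978	end of LOC414039 to start of LOC725387	33977	Amel_HAv3_1_reFlye	34179
Chr1_gap6	8670	LOC410685	64235	Amel_HAv3_1_reND	52788
Chr1_gap8	4869	LOC410674	142134	Amel_HAv3_1_reFlye	142302
Chr1_gap9	25	LOC410785	268848	Amel_HAv3_1_reFlye	266084
Chr2_gap1	19249	end of LOC102656216 to start of LOC100577827	128592	Amel_HAv3_1_reND	121580
Chr3_gap1	25238	LOC410967	145799	ASM1384120v1	139551
Chr8_gap1	35434	end of LOC411959 to start of LOC725220	67050	ASM1384124v1	78460
Chr8_gap3	4493	start of LOC100578698 to end of LOC100578828	87698	Amel_HAv3_1_reFlye	92821
Chr8_gap4	2636	AChE-2	134893	Amel_HAv3_1_reND	134907
Chr10_gap6	158704	start of LOC102654940 to start of LOC409869	200539	ASM1384124v1	203381
Chr16_gap1	56203	start of Mir993 to start of LOC410648	136683	Amel_HAv3_1_reND	142661
Chr16_gap2	25	LOC410655	214928	Amel_HAv3_1_reFlye	221629
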