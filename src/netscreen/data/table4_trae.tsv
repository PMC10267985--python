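trae	exposure_events	exposure_n	exposure_pct	nonexposure_events	nonexposure_n	nonexposure_pct
Leukopenia	10	50	20	19	47	40
Hepatotoxicity	16	50	32	14	47	30
Nausea	20	50	40	29	47	62
Diarrhea	9	50	18	20	47	43
Fatigue	16	50	32	27	47	57
Appetite loss	18	50	36	28	47	60
Hair loss	7	50	14	12	47	26
Hand-foot syndrome	13	50	26	17	47	36
Rash	12	50	24	10	47	21
Hypertension	11	50	22	14	47	30
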