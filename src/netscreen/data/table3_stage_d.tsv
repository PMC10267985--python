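id	time_days	event	arm
case1	106	1	exposure
case2	94	1	exposure
case3	82	1	exposure
case4	165	1	exposure
case5	529	1	exposure
case6	157	1	nonexposure
case7	64	1	nonexposure
case8	61	1	nonexposure
case9	67	1	nonexposure
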