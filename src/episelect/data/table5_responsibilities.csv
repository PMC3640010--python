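case,p_c0,p_c1,outcome
1,0.08417,0.91583,seizure_free
2,0.98861,0.01139,seizure_free
3,0.95076,0.04924,seizure_free
4,0.06282,0.93718,improvement_only
5,0.59592,0.40408,seizure_free
6,0.01103,0.98897,improvement_only
7,0.99529,0.00471,seizure_free
8,0.0332,0.9668,improvement_only
9,0.5379,0.4621,seizure_free
10,0.01391,0.98609,improvement_only
11,0.00381,0.99619,seizure_free
12,0.95596,0.04404,seizure_free
13,0.93247,0.06753,seizure_free
14,0.5171,0.4829,seizure_free
15,0.00944,0.99056,improvement_only
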