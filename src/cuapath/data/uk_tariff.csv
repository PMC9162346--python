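term,value
any_dysfunction,0.081
mobility_2,0.069
mobility_3,0.314
selfcare_2,0.104
selfcare_3,0.214
usual_activities_2,0.036
usual_activities_3,0.094
pain_discomfort_2,0.123
pain_discomfort_3,0.386
anxiety_depression_2,0.071
anxiety_depression_3,0.236
any_level3,0.269
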