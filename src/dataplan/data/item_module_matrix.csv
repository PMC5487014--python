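Item,Module 2,Module 3,Module 4,Module 5,Module 6,Module 7
Felt irritable,1,1,0,0,0,0
Felt restless,0,1,0,0,0,0
Felt worried,0,0,1,0,0,0
Felt worthless or guilty,1,0,1,0,0,0
Experienced loss of interest or pleasure,1,0,0,1,0,0
Felt hopeless,1,1,1,0,0,0
Felt down or depressed,1,1,0,0,0,0
Felt fatigued,0,0,0,0,1,0
Experienced muscle tension,0,0,0,0,1,0
Had difficulty concentrating,0,1,0,0,0,0
Avoided activities,0,0,0,1,0,1
Sought reassurance,0,0,0,1,0,1
Procrastinated,0,0,0,1,0,1
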