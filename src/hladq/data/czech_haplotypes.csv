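dqa1,dqb1,frequency,predisposing
DQA1*05,DQB1*02,0.092,true
DQA1*02,DQB1*02,0.083,true
DQA1*03,DQB1*03:02,0.069,true
DQA1*05,DQB1*03:01,0.140,false
DQA1*03,DQB1*03:01,0.070,false
DQA1*03,DQB1*03:03,0.030,false
DQA1*02,DQB1*03:03,0.010,false
DQA1*01,DQB1*05:01,0.160,false
DQA1*01,DQB1*05:02,0.050,false
DQA1*01,DQB1*05:03,0.040,false
DQA1*01,DQB1*06:02,0.130,false
DQA1*01,DQB1*06:03,0.060,false
DQA1*04,DQB1*04:02,0.050,false
DQA1*06,DQB1*03:01,0.016,false
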