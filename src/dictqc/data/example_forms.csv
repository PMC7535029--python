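Group ID,Description
B100,Specimen Tracking Form
BSCR,Subject Screening Log
C100,Specimen Tracking Form
F1,Eligibility and Enrollment Form
F101,Dual Energy X-Ray Absorptiometry Form
F15,Pregnancy Result Form
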