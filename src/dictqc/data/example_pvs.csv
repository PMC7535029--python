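Permissible Value ID,Permissible Value,Permissible Value Description,Data Element ID
1,1,Viral Breakthrough,OFFTXR
2,2,Adverse Reaction,OFFTXR
3,3,Subject's Decision,OFFTXR
4,4,Clinician's Decision,OFFTXR
5,5,Course Completed,OFFTXR
99,99,Other,OFFTXR
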