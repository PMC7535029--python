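Data Element Description,Data Element ID,Data Type,Length,Group ID
Antiretroviral therapy during L & D?,ARTDLD,CHAR,3,Eligibility Questionnaire
Birth Weight (grams),BRTWT,NUMBER,4,Eligibility Questionnaire
Derived Age,DAGE,NUMBER,5,Eligibility Questionnaire
HIV Method,HIVMTD,CHAR,66,Eligibility Questionnaire
Is the subject HIV infected?,HIVINF,CHAR,3,Eligibility Questionnaire
Any Immunizations?,IMMNYN,CHAR,7,Infant Non-Study Medications
Test Value,TSTVLU,NUMBER,12,Laboratory Results
Date started,ONSETD,DATE,8,Medical Events
Specimen obtained for confirmatory test?,CNFTYN,CHAR,3,Syphilis Test Result
Years of formal education,YRSEDC,NUMBER,2,Maternal Demographics
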