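system,code,label
read2,R090.,nausea
read2,R0904,vomiting
read2,1B1B.,headache
read2,R0051,dizziness
read2,1BX2.,dry mouth
read2,R0083,drowsiness
read2,1B1Q.,insomnia
read2,19C..,diarrhoea
read2,19E..,constipation
read2,1D14.,sweating
read2,E2781,sexual dysfunction
read2,R0041,tremor
read2,1B13.,fatigue
read2,R0502,palpitations
read2,1612.,appetite loss
ctv3,X76Cf,nausea
ctv3,XM0CT,vomiting
ctv3,XM0CV,headache
ctv3,X76Dm,dizziness
ctv3,XaXSL,dry mouth
ctv3,XM0CW,drowsiness
ctv3,XaIP6,insomnia
ctv3,XaXR0,diarrhoea
ctv3,Xa9Bu,constipation
ctv3,XM0Cn,sweating
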