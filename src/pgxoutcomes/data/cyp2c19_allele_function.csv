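star_allele,function,activity
*1,normal,
*2,no_function,
*3,no_function,
*4,no_function,
*5,no_function,
*6,no_function,
*7,no_function,
*8,no_function,
*9,decreased,
*12,unknown,
*17,increased,
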