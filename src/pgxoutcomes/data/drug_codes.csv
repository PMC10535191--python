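system,code,label,pattern
name,,ssri_citalopram,\bcitalopram\b
name,,ssri_escitalopram,\bescitalopram\b
name,,ssri_sertraline,\bsertraline\b
name,,other_antidepressant,\bfluoxetine\b
name,,other_antidepressant,\bparoxetine\b
name,,other_antidepressant,\bfluvoxamine\b
name,,other_antidepressant,\bvenlafaxine\b
name,,other_antidepressant,\bduloxetine\b
name,,other_antidepressant,\bmirtazapine\b
name,,other_antidepressant,\bamitriptyline\b
name,,other_antidepressant,\bnortriptyline\b
name,,other_antidepressant,\bimipramine\b
name,,other_antidepressant,\blofepramine\b
name,,other_antidepressant,\bdosulepin\b
name,,other_antidepressant,\btrazodone\b
name,,antipsychotic,\bquetiapine\b
name,,antipsychotic,\bolanzapine\b
name,,antipsychotic,\brisperidone\b
name,,antipsychotic,\baripiprazole\b
name,,antipsychotic,\bhaloperidol\b
name,,antipsychotic,\bchlorpromazine\b
bnf,0403030D0,ssri_citalopram,
bnf,0403030X0,ssri_escitalopram,
bnf,0403030Q0,ssri_sertraline,
bnf_prefix,040301,other_antidepressant,
bnf_prefix,040302,other_antidepressant,
bnf_prefix,040304,other_antidepressant,
bnf_prefix,0402,antipsychotic,
dmd,321988004,ssri_citalopram,
dmd,321955008,ssri_escitalopram,
dmd,321962006,ssri_sertraline,
read2,da75.,ssri_citalopram,
read2,da77.,ssri_escitalopram,
read2,da76.,ssri_sertraline,
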