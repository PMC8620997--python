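drug	gene
amitriptyline	CYP2C19
clomipramine	CYP2C19
doxepin	CYP2C19
imipramine	CYP2C19
trimipramine	CYP2C19
citalopram	CYP2C19
escitalopram	CYP2C19
sertraline	CYP2C19
amitriptyline	CYP2D6
clomipramine	CYP2D6
duloxetine	CYP2D6
doxepin	CYP2D6
fluoxetine	CYP2D6
fluvoxamine	CYP2D6
paroxetine	CYP2D6
sertraline	CYP2D6
mirtazapine	CYP2D6
venlafaxine	CYP2D6
aripiprazole	CYP2D6
clozapine	CYP2D6
fluphenazine	CYP2D6
haloperidol	CYP2D6
olanzapine	CYP2D6
perphenazine	CYP2D6
pimozide	CYP2D6
risperidone	CYP2D6
zuclopenthixol	CYP2D6
thioridazine	CYP2D6
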