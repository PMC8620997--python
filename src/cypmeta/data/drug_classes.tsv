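drug	drug_class
paroxetine	SSRI
fluoxetine	SSRI
fluvoxamine	SSRI
citalopram	SSRI
escitalopram	SSRI
sertraline	SSRI
venlafaxine	SNRI
duloxetine	SNRI
mirtazapine	other_antidepressant
bupropion	other_antidepressant
amitriptyline	TCA
clomipramine	TCA
imipramine	TCA
doxepin	TCA
trimipramine	TCA
aripiprazole	antipsychotic
clozapine	antipsychotic
fluphenazine	antipsychotic
haloperidol	antipsychotic
olanzapine	antipsychotic
perphenazine	antipsychotic
pimozide	antipsychotic
risperidone	antipsychotic
zuclopenthixol	antipsychotic
thioridazine	antipsychotic
chlorpromazine	antipsychotic
prochlorperazine	antipsychotic
omeprazole	other
esomeprazole	other
lansoprazole	other
ticlopidine	other
terbinafine	other
quinidine	other
cinacalcet	other
amiodarone	other
ritonavir	other
moclobemide	other
modafinil	other
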