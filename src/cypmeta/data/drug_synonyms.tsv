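proprietary	generic
seroxat	paroxetine
paxil	paroxetine
prozac	fluoxetine
oxactin	fluoxetine
cipramil	citalopram
celexa	citalopram
cipralex	escitalopram
lustral	sertraline
zoloft	sertraline
efexor	venlafaxine
effexor	venlafaxine
tryptizol	amitriptyline
elavil	amitriptyline
anafranil	clomipramine
surmontil	trimipramine
tofranil	imipramine
sinequan	doxepin
cymbalta	duloxetine
zispin	mirtazapine
faverin	fluvoxamine
zyprexa	olanzapine
risperdal	risperidone
haldol	haloperidol
abilify	aripiprazole
clozaril	clozapine
largactil	chlorpromazine
stemetil	prochlorperazine
orap	pimozide
clopixol	zuclopenthixol
fentazin	perphenazine
modecate	fluphenazine
melleril	thioridazine
losec	omeprazole
prilosec	omeprazole
nexium	esomeprazole
zoton	lansoprazole
ticlid	ticlopidine
zyban	bupropion
wellbutrin	bupropion
lamisil	terbinafine
cordarone	amiodarone
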