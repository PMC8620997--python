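drug	gene
bupropion	CYP2D6
quinidine	CYP2D6
terbinafine	CYP2D6
cinacalcet	CYP2D6
amiodarone	CYP2D6
ritonavir	CYP2D6
omeprazole	CYP2C19
esomeprazole	CYP2C19
lansoprazole	CYP2C19
ticlopidine	CYP2C19
moclobemide	CYP2C19
modafinil	CYP2C19
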