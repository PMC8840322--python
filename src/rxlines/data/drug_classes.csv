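molecule,formulation,drug_class,default_days_supply
chlorpromazine,oral,ORAL_TYPICAL,30
periciazine,oral,ORAL_TYPICAL,30
haloperidol,oral,ORAL_TYPICAL,30
aripiprazole,oral,ORAL_ATYPICAL,30
olanzapine,oral,ORAL_ATYPICAL,30
quetiapine,oral,ORAL_ATYPICAL,30
risperidone,oral,ORAL_ATYPICAL,30
ziprasidone,oral,ORAL_ATYPICAL,30
paliperidone,oral,ORAL_ATYPICAL,30
brexpiprazole,oral,ORAL_ATYPICAL,30
amisulpride,oral,ORAL_ATYPICAL,30
asenapine,oral,ORAL_ATYPICAL,30
lurasidone,oral,ORAL_ATYPICAL,30
flupenthixol,depot,TYPICAL_LAT,28
zuclopenthixol,depot,TYPICAL_LAT,28
haloperidol,depot,TYPICAL_LAT,28
paliperidone,depot,ATYPICAL_LAT,28
aripiprazole,depot,ATYPICAL_LAT,28
risperidone,depot,ATYPICAL_LAT,28
olanzapine,depot,ATYPICAL_LAT,28
clozapine,oral,CLOZAPINE,30
amitriptyline,oral,ANTIDEPRESSANT,30
citalopram,oral,ANTIDEPRESSANT,30
desvenlafaxine,oral,ANTIDEPRESSANT,30
dosulepin,oral,ANTIDEPRESSANT,30
doxepin,oral,ANTIDEPRESSANT,30
duloxetine,oral,ANTIDEPRESSANT,30
escitalopram,oral,ANTIDEPRESSANT,30
fluoxetine,oral,ANTIDEPRESSANT,30
imipramine,oral,ANTIDEPRESSANT,30
mianserin,oral,ANTIDEPRESSANT,30
mirtazapine,oral,ANTIDEPRESSANT,30
moclobemide,oral,ANTIDEPRESSANT,30
nortriptyline,oral,ANTIDEPRESSANT,30
paroxetine,oral,ANTIDEPRESSANT,30
phenelzine,oral,ANTIDEPRESSANT,30
reboxetine,oral,ANTIDEPRESSANT,30
sertraline,oral,ANTIDEPRESSANT,30
tranylcypromine,oral,ANTIDEPRESSANT,30
venlafaxine,oral,ANTIDEPRESSANT,30
lithium,oral,LITHIUM,30
valproate,oral,ANTIEPILEPTIC,30
carbamazepine,oral,ANTIEPILEPTIC,30
lamotrigine,oral,ANTIEPILEPTIC,30
levetiracetam,oral,ANTIEPILEPTIC,30
topiramate,oral,ANTIEPILEPTIC,30
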