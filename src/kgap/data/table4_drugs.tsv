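name	struct_id	pubchem_cid	in_lincs
amantadine	144	2130	true
apomorphine	228	6005	true
benzatropine	333	1201549	true
biperiden	374	2381	true
bromocriptine	403	31101	true
dexetimide	831	30843	false
entacapone	1018	5281081	true
levodopa	1567	6047	true
melevodopa	1673	23497	false
metixene	1780	4167	true
opicapone	5143	135565903	false
orphenadrine	1999	4601	true
pergolide	2105	47811	true
pimavanserin	5142	10071196	true
piribedil	2202	4850	true
pramipexole	2233	119570	true
procyclidine	2276	4919	true
rasagiline	3521	3052776	true
rivastigmine	2392	77991	true
ropinirole	2402	5095	true
rotigotine	2407	59227	true
safinamide	4921	131682	true
selegiline	2429	26757	true
tolcapone	2697	4659569	true
trihexyphenidyl	2745	5572	true
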