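concept_id	name
omop:4030041	Parkinsonism
omop:4030042	Parkinson's disease
omop:4030043	Arteriosclerotic Parkinsonism
omop:4030044	Dementia associated with Parkinson's Disease
omop:4030045	Neuroleptic-induced Parkinsonism
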