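cohort,stratum,n_records
discovery,all,269065
evaluation,malignant,767
evaluation,benign,12485
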