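relation	role	concept_fsn	direction	sctid
has-natural-child	object	sct_Natural-child_person	both
natural-parent-of	subject	sct_Natural-parent_person	both
natural-sibling-of	subject	sct_Natural-sibling_person	both
natural-niece-of	subject	sct_Niece_person	to_sct
natural-nephew-of	subject	sct_Nephew_person	to_sct
natural-maternal-grandparent-of	subject	sct_Maternal-grandparent_person	to_sct
natural-paternal-grandparent-of	subject	sct_Paternal-grandparent_person	to_sct
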