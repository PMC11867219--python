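# UK-Biobank-derived cohort composition for four cancers, used by the
# Monte-Carlo power engine.  Conditional proportions:
#   p_female            P(female)
#   p_case_female       P(case | female)
#   p_case_male         P(case | male)
#   p_fh_female_control P(positive first-degree family history | female control)
#   p_fh_female_case    P(FH | female case)
#   p_fh_male_control   P(FH | male control)
#   p_fh_male_case      P(FH | male case)
cancer	p_female	p_case_female	p_case_male	p_fh_female_control	p_fh_female_case	p_fh_male_control	p_fh_male_case
breast	0.54	0.079	0.00049	0.11	0.18	0.10	0.16
prostate	0.54	0	0.061	0.081	0	0.077	0.15
bowel	0.54	0.013	0.021	0.11	0.15	0.12	0.18
lung	0.54	0.0077	0.0099	0.13	0.23	0.13	0.22
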