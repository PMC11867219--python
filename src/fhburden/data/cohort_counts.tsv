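# Realized case/control counts by sex in the UK-Biobank-derived exome cohort
# (419,307 samples: 227,393 females, 191,914 males).  Controls for a cancer are
# all samples without that cancer.
cancer	female_controls	female_cases	male_controls	male_cases
breast	209435	17958	191820	94
prostate	227393	0	180249	11665
bowel	224404	2989	187956	3958
lung	225641	1752	190009	1905
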