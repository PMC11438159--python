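#name	pattern	category	citation
polyA_signal_AATAAA	AATAAA	negative_cis	Proudfoot & Brownlee 1976
polyA_signal_ATTAAA	ATTAAA	negative_cis	Sheets et al. 1990
ARE_instability_ATTTA	ATTTA	negative_cis	Shaw & Kamen 1986
splice_donor_GGTAAG	GGTAAG	negative_cis	Mount 1982
splice_donor_GGTGAT	GGTGAT	negative_cis	Mount 1982
splice_acceptor	YYYYNCAGG	negative_cis	Mount 1982
chi_site	GCTGGTGG	negative_cis	Smith et al. 1981
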