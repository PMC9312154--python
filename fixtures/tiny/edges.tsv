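mr0000	mRNA	mr0002	mRNA
mr0000	mRNA	mr0004	mRNA
mr0000	mRNA	mi0001	miRNA
mr0000	mRNA	ln0000	lncRNA
mr0001	mRNA	mr0002	mRNA
mr0001	mRNA	mr0003	mRNA
mr0001	mRNA	mr0004	mRNA
mr0001	mRNA	mr0005	mRNA
mr0002	mRNA	mr0003	mRNA
mr0002	mRNA	mr0004	mRNA
mr0003	mRNA	mr0004	mRNA
mr0003	mRNA	mr0005	mRNA
mr0003	mRNA	mi0000	miRNA
mr0003	mRNA	mi0002	miRNA
mr0004	mRNA	mr0005	mRNA
mr0004	mRNA	mi0000	miRNA
mr0004	mRNA	mi0001	miRNA
mr0004	mRNA	ln0000	lncRNA
mr0004	mRNA	ln0001	lncRNA
mi0000	miRNA	mi0001	miRNA
mi0000	miRNA	mi0002	miRNA
mi0001	miRNA	mi0002	miRNA
mi0002	miRNA	ln0002	lncRNA
ln0000	lncRNA	ln0002	lncRNA
ln0001	lncRNA	ln0002	lncRNA
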