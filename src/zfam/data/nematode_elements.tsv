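element	iupac
daf-16	GTAAACAC
pqm-1	ACTGATAA
fkh-2	RTAAACA
daf-12	GWGYGYGTGTGYGT
hsf-1	TTCYAGAA
xbp-1	WTACGTG
lin-14	GAACRC
elt-3	TCTTATCA
ets-7	AACCGGAAGT
jun-1	ATGACTCA
hif-1	TYACGTGAC
lin-48	CCGTTAY
dmd-10	AATGTTTC
atfs-1	ATGATGCAAW
elt-2	TCTTATCA
elt-7	TGATAAC
ceh-18	TGCATAWT
fos-1	TGACTCA
ceh-60	TGATTGACA
ceh-36	GGATTA
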