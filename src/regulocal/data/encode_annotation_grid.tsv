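SNP	promoter_histone	enhancer_histone	dnase	protein_bound
rs10889356	X	.	X	X
rs9436661	X	.	.	.
rs1168046	.	X	.	.
rs10789117	.	X	.	.
rs10889344	.	X	.	.
rs11207979	.	X	.	.
rs1168047	.	X	.	.
rs12029068	X	.	.	.
rs638714	X	.	.	.
rs6690733	.	X	.	.
rs9436221	X	.	.	.
rs9436222	X	.	.	.
rs4587594	.	.	X	.
rs6678483	.	X	.	.
rs11207997	.	X	.	.
rs12090886	.	X	.	.
rs1168045	.	X	.	.
rs1627591	.	X	.	.
rs10889337	.	X	.	.
rs10493322	X	.	X	.
rs1168114	.	X	X	X
rs1168113	.	X	X	X
rs12136083	.	X	.	.
rs6679002	.	X	.	.
rs12130333	.	X	.	.
rs10889377	.	X	.	.
rs17123817	.	X	.	.
rs10889378	.	X	.	.
rs13375691	.	.	X	X
rs646179	.	.	X	X
rs9436223	X	.	.	.
rs631106	X	.	.	X
rs626787	X	.	.	.
rs10889347	.	.	.	(X)
rs6587980	.	.	.	(X)
rs1184547	.	.	.	(X)
rs10157265	.	.	.	(X)
rs1168015	.	.	(X)	(X)
rs12062275	.	.	.	(X)
rs10889336	.	.	(X)	(X)
rs1168042	.	.	(X)	(X)
rs12037659	.	.	.	(X)
rs11207976	.	.	.	(X)
rs1184865	.	.	.	(X)
rs11207992	.	.	.	(X)
rs10889352	.	(X)	.	.
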