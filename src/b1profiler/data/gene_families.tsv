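family_id	gene_symbol	role	domain_scope	strict_tier
TIGR00190	thiC	synthesis	both	true
PF01964	thiC	synthesis	both	true
TIGR00097	thiD	synthesis	both	true
B1HMM_thiDN	thiDN	synthesis	archaea	true
TIGR00693	thiE	synthesis	bacteria	true
TIGR02351	thiG	synthesis	bacteria	true
PF04127	thi4	synthesis	both	true
TIGR01379	thiL	synthesis	both	true
B1HMM_thiN	thiN	synthesis	archaea	true
B1HMM_thiK	thiK	salvage	bacteria	true
TIGR00694	thiM	salvage	bacteria	true
PF03070	tenA	salvage	both	true
TIGR02357	thiT	transport	bacteria	true
TIGR01254	thiB	transport	bacteria	true
TIGR01253	thiP	transport	bacteria	true
TIGR01255	thiQ	transport	bacteria	true
B1HMM_thiX	thiX	transport	bacteria	true
B1HMM_thiY	thiY	transport	bacteria	true
B1HMM_thiZ	thiZ	transport	bacteria	true
B1HMM_cytX	cytX	transport	both	true
B1HMM_ykoC	ykoC	transport	bacteria	true
B1HMM_ykoD	ykoD	transport	bacteria	true
B1HMM_ykoE	ykoE	transport	bacteria	true
B1HMM_ykoF	ykoF	transport	bacteria	true
B1HMM_omr1	omr1	transport	both	true
K10944	amoA	chemoautotrophy	archaea	true
K00371	nxr	chemoautotrophy	bacteria	true
K00394	aprA	chemoautotrophy	bacteria	false
K00395	aprB	chemoautotrophy	bacteria	false
K11180	dsrA	chemoautotrophy	bacteria	false
K01601	rbcL	chemoautotrophy	bacteria	true
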