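sequence	accession	nterm_type	log2_mean	log2_sem	qualitative
SDMPPLTLEGIQDR	O14561	TP-removal	1.25	0.44
LHLGVTPSVIR	O14773	TP-removal			DA_only
STQAATQVVLNVPETR	O75439	ragging TP-removal	0.92	0.26
SSEAPPLINEDVKR	P04843	ragging TP-removal	0.65	0.05
DAPEEEDHVLVLR	P07237	TP-removal	0.98	0.24
AKDVKFGADAR	P10809	TP-removal	0.72	0.04
VNFTVDQIR	P13639	Met-removal	0.67	0.07
DDEVDVDGTVEEDLGKSR	P14625	TP-removal			DA_only
KEAESSPFVER	P14625	Internal			DA_only
ASGANFEYIIAEKR	P30084	TP-removal	0.69	0.08
SDVLELTDDNFESR	P30101	TP-removal	1.29	0.45
DDLVTVKTPAFAESVTEGDVR	P36957	TP-removal	0.77	0.14
VLLESEQFLTELTR	P37108	Met-removal	0.67	0.09
DGVGGDPAVALPHR	P49257	TP-removal	1.09	0.42
LRPGDCEVCISYLGR	P55145	TP-removal			DA_only
SASVVSVISR	P61803	Met-removal	0.71	0.08
ESETTTSLVLER	Q04837	TP-removal	0.75	0.07
VMEKPSPLLVGR	Q13283	Met-removal	0.77	0.05
LSQTQGPPDYPR	Q13405	Internal	0.80	0.09
AAVAATAAAKGNGGGGGR	Q6Y1H2	Met-removal	0.67	0.07
AATLILEPAGR	Q86TX2	Met-removal	0.67	0.07
AADTQVSETLKR	Q92616	Met-removal	0.84	0.19
RASPAGGPLEDVVIER	Q96AY3	ragging TP-removal	0.84	0.16
SEVPGAAAEGSGGSGVGIGDR	Q9NPA0	TP-removal	0.79	0.21
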