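sequence	accession	nterm_type	log2_mean	log2_sem	qualitative
VHQSVATDGPSSTQPALPKAR	O75251	ragging TP-removal			CTRL_only
LAADVGKAGAER	P05141	Internal	-1.65	0.60
GNLANVIR	P05141	Internal			CTRL_only
AQTSPSPKAGAATGR	P06576	TP-removal	-0.70	0.12
EICGPGIDIR	P08069	TP-removal			CTRL_only
MAPEVLPKPR	P09669	Natural	-0.87	0.26
APEVLPKPR	P09669	ragging TP-removal	-0.70	0.12
TSTAPAASPNVR	P11498	ragging TP-removal	-0.72	0.08
LAADVGKSGTER	P12236	Internal	-2.57	0.67
NQSPVDQGATGASQGLLDR	P18827	Internal	-0.72	0.08
SHGSQETDEEFDAR	P20674	TP-removal	-0.74	0.15
VAHFTFQPDPEPR	P21953	TP-removal			CTRL_only
VSKPTLKEVVIVSATR	P24752	TP-removal	-0.74	0.11
QKTGTAEMSSILEER	P25705	TP-removal	-0.69	0.10
AIAAKEKDIQEESTFSSR	P42704	TP-removal	-0.69	0.08
ADCISEPVNR	P43304	TP-removal	-1.35	0.27
SHTDIKVPDFSEYR	P47985	TP-removal			CTRL_only
MKEGMSNNSTTSISQAR	P50150	Met-removal	-0.81	0.15
APSVPAAEPEYPKGIR	P54819	Met-removal	-0.66	0.05
SVPAAEPEYPKGIR	P54819	ragging TP-removal			CTRL_only
GVQVETISPGDGR	P62942	Met-removal	-0.59	0.16
STAVYSATPVPTPSLPER	P82673	TP-removal (new)	-0.71	0.11
SETTTSLVLER	Q04837	ragging TP-removal			CTRL_only
TVNSLNVSANEN	Q13740	Internal			CTRL_only
AELPPVPGGPR	Q14249	TP-removal			CTRL_only
STNVQKEGQGSQTLR	Q6PML9	Internal	-0.70	0.06
GAPEVLVSAPR	Q7Z4H8	TP-removal	-0.73	0.12
GGSCPHPSSAPR	Q8WY21	TP-removal			CTRL_only
STLQEVVGIR	Q969P0	Internal			CTRL_only
EEQPPETAAQR	Q96HE7	TP-removal	-0.68	0.07
HGEEQPPETAAQR	Q96HE7	ragging TP-removal			CTRL_only
SAPGEDEECGR	Q99523	Propeptide-removal			CTRL_only
TTFNIQDGPDFQDR	Q99757	TP-removal	-0.72	0.12
LHTAVVSTPPR	Q9BW92	TP-removal (new)			CTRL_only
YSKSPSNKDAALLEAAR	Q9H078	Internal			CTRL_only
LHTAANAAATATETTCQDVAATPVAR	Q9NP92	Internal	-0.72	0.08
SCPGTVAKDLR	Q9NVV4	ragging TP-removal			CTRL_only
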