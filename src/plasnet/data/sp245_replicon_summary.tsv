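replicon_id	length_bp	gc_percent	total_proteins	unconnected	connected	percent_connected
AZOBR1	1766028	68.6	1748	1504	244	13.96
AZOBR2	912449	68.3	884	715	169	19.12
AZOBR3	778798	68.2	808	661	147	18.19
AZOBR4	690334	68.9	671	535	136	20.27
AZOBR5	191828	66.7	162	133	29	17.90
AZOBR6	167364	66.8	125	104	21	16.80
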