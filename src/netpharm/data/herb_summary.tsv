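herb	n_compounds	n_bioactive	n_targets
Radix Angelicae Sinensis	105	2	54
Rhizoma Ligustici	108	7	30
Radix Ginseng	190	22	118
Rhizoma Curcumae	81	3	24
Cortex Moutan	55	11	173
Radix Achyranthis Bidentatae	176	20	187
Cortex Cinnamomi	100	0	0
Radix Paeoniae Alba	85	13	95
Radix Glycyrrhizae	280	93	238
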