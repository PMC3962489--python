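# Marker panel counts from the published screen of synthetic allotetraploid
# Mimulus progeny: pooled selfed (S2) classes and per-marker backcross (BC1N)
# counts. n_loss_excl excludes the single outlier individual carrying six
# of the ten observed losses.
marker_id	arm_label	class	n_scored	n_het	n_loss	n_loss_excl
S2G_pooled	NA	S2G	309	309	0	0
S2N_pooled	NA	S2N	308	308	0	0
MgSTS_98	1, Left arm	BC1N	48	46	2	1
MgSTS_787	2, Left arm	BC1N	48	47	1	0
MgSTS_724	6, Left arm	BC1N	48	45	3	2
MgSTS_376	7, Left arm	BC1N	48	48	0	0
MgSTS_358	11, Right arm	BC1N	48	47	1	0
MgSTS_780	11, Left arm	BC1N	48	47	1	0
MgSTS_847	1, Left arm	BC1N	48	46	2	1
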