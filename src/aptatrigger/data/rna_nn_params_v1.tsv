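# aptatrigger nearest-neighbor RNA free-energy parameters, version v1
# Units: kcal/mol at 37 C, 1.0 M Na+, 0 M Mg2+.
# Watson-Crick stack entries follow Xia et al. 1998 / Turner 2004; wobble
# (GU) stacks are set within the published range. Loop initiations are
# Turner-style; sizes beyond the tabulated maximum are extrapolated with a
# Jacobson-Stockmayer term lxc * rt * ln(n / n_max).
# stack key XYWZ: closing pair X:Y stacked on inner pair W:Z, geometry
# 5'-X W-3' / 3'-Y Z-5'. The loader symmetrizes (X,Y),(W,Z) == (Z,W),(Y,X).
category	key	value
stack	AUAU	-0.93
stack	AUUA	-1.10
stack	UAAU	-1.33
stack	CGAU	-2.11
stack	CGUA	-2.08
stack	GCAU	-2.35
stack	GCUA	-2.24
stack	CGGC	-2.36
stack	CGCG	-3.26
stack	GCCG	-3.42
stack	AUGU	-0.80
stack	AUUG	-1.00
stack	UAGU	-1.00
stack	UAUG	-0.80
stack	CGGU	-1.50
stack	CGUG	-2.10
stack	GCGU	-2.20
stack	GCUG	-1.40
stack	GUGU	-0.50
stack	GUUG	0.50
stack	UGGU	-0.60
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
internal	2	1.50
internal	3	1.60
internal	4	1.70
internal	5	1.80
internal	6	2.00
misc	terminal_au	0.50
misc	ml_closing	3.40
misc	ml_unpaired	0.00
misc	ml_branch	0.40
misc	internal_asym	0.60
misc	internal_asym_max	3.00
misc	duplex_init	4.09
misc	rt	0.61633
misc	lxc	1.75
misc	min_hairpin	3
misc	max_loop	30
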