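class	Apidae sensu lato	Megachile + Apidae sensu strictu	Apidae sensu strictu	Centris + Corbiculate bees	Corbiculate bees	Meliponini	Bombini
linear alkane	96.9	99.0	98.8	95.2	70.8	94.2	72.8
branched alkane	47.5	69.2	73.4	68.4	44.3	60.3	79.3
alkene	61.8	72.7	55.5	83.7	90.4	86.2	94.7
alkadiene	0.8	0.0	0.0	0.0	0.0	0.0	0.1
aldehyde	0.8	0.2	0.8	9.3	1.4	0.2	8.7
alcohol	1.4	1.4	9.3	0.8	0.1	0.0	0.0
fatty acid	99.0	99.3	95.7	49.7	50.3	0.4	0.4
keto acid	0.0	0.0	0.0	0.0	3.7	0.0	0.0
ester	52.4	36.5	38.3	62.2	65.0	51.8	51.0
terpene	1.1	0.0	4.6	54.1	54.1	0.0	0.0
terpene alcohol	0.0	0.0	0.1	9.3	1.4	0.0	8.7
lactone	3.7	0.0	0.0	0.0	0.0	0.0	0.0
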