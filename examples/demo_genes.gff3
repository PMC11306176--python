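##gff-version 3
# synthetic gene annotation for the demo (coordinates invented)
1	demo	gene	2500000	2650000	.	+	.	ID=gene:DEMO_G1;Name=ALPHA1;description=synthetic gene near the first planted tract
1	demo	gene	12500000	12700000	.	-	.	ID=gene:DEMO_G2;Name=BETA2;description=synthetic gene inside the second tract
2	demo	gene	19800000	20150000	.	+	.	ID=gene:DEMO_G3;Name=GAMMA3;description=synthetic gene spanning the sweep core
2	demo	gene	25000000	25100000	.	+	.	ID=gene:DEMO_G4
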