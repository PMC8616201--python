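# Optical properties of the seven segmented brain tissue classes at 635 nm.
# Interaction coefficients are per mm; the refractive index is shared by all
# cerebral tissue subtypes (1.40).  Label 0 is the extracranial background,
# where photon packets are treated as escaped.
# version: 1
# columns: label	name	mu_a	mu_s	g	n_ri
0	background	0.0	0.0	0.0	1.0
1	csf	0.004	0.009	0.89	1.40
2	grey_matter	0.13	9	0.92	1.40
3	white_matter	0.08	40.5	0.85	1.40
4	necrotic	0.17	24.1	0.9	1.40
5	non_enhancing	0.08	69.7	0.9	1.40
6	enhancing	0.17	24.1	0.9	1.40
7	oedema	0.08	40.5	0.85	1.40
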