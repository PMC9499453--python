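# Fingerprint peak inventory of the eight fentanyl analogs: DFT-simulated
# peak position with qualitative strength label, measured THz peak position,
# the tabulated shift (DFT - experimental), and the vibrational-mode label.
# Columns: analyte, dft_freq_thz, dft_label, exp_freq_thz, shift_thz, mode
fentanyl	0.85	w	0.92	-0.07	δring
fentanyl	1.40	w	1.38	0.02	δring
fentanyl	1.87	w	1.78	0.09	δ(C-C)
fentanyl	2.53	w	2.52	0.01	δring
fentanyl	2.79	w	2.83	-0.04	δring
fentanyl	3.35	w	3.27	0.08	δring
methoxyacetylfentanyl	1.07	w	1.11	-0.04	δ(C-C) oop
methoxyacetylfentanyl	1.38	w	1.35	0.03	δ(C-C-C) oop
methoxyacetylfentanyl	2.61	w	2.62	-0.01	δring
acetylfentanyl	1.02	w	1.07	-0.05	δring
acetylfentanyl	1.41	m	1.34	0.07	δ(C-C)opp
acetylfentanyl	2.34	w	2.36	-0.02	δring
furanylfentanyl	0.79	s	0.83	-0.04	δ(C-C)ip
furanylfentanyl	1.22	m	1.17	0.05	δ(C-C)opp
furanylfentanyl	1.70	m	1.70	0	δring
furanylfentanyl	2.55	vs	2.50	0.05	δring
furanylfentanyl	2.99	w	2.93	0.06	δring
butyrylfentanyl	0.56	w	0.52	0.01	δring
butyrylfentanyl	1.01	vs	1.07	-0.06	δ(C-C)opp
butyrylfentanyl	2.01	w	1.99	0.02	δring
4-fluoroisobutyrfentanyl	1.20	m	1.19	0.01	δ(C-C)opp
4-fluoroisobutyrfentanyl	1.51	m	1.57	-0.06	δ(C-N)ip
4-fluoroisobutyrfentanyl	2.12	s	2.11	0.01	δ(C-C)opp
carfentanil	1.19	w	1.14	0.05	δring
carfentanil	1.94	m	2.00	-0.06	δring
carfentanil	2.48	m	2.52	-0.04	δring
carfentanil	3.49	m	3.45	0.04	δ(C-C)opp
valerylfentanyl	0.91	m	0.91	0	δ(C-N)opp
valerylfentanyl	1.97	m	1.96	0.01	δ(C-C)opp
valerylfentanyl	2.26	m	2.26	0	δ(C-C-C)opp
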