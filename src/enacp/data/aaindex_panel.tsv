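# Default physicochemical index panel for the autocorrelation encoders
# (auto/cross covariance and physicochemical distance transformation).
# Eight classical per-residue scales, AAindex-style:
#   hydrophobicity   - Tanford/Chou consensus hydrophobicity
#   hydrophilicity   - Hopp-Woods hydrophilicity
#   side_chain_mass  - side-chain mass (Da)
#   polarity         - Grantham polarity
#   polarizability   - Charton-Charton polarizability
#   net_charge_index - net charge index of side chains
#   solvent_access   - relative solvent-accessible surface area (tripeptide)
#   flexibility      - Bhaskaran-Ponnuswamy average flexibility
# Raw values; standardized (zero mean, unit population sd over the 20
# letters) before entering any encoder. User-supplied AAindex-style flat
# files may replace or extend this panel.
aa	hydrophobicity	hydrophilicity	side_chain_mass	polarity	polarizability	net_charge_index	solvent_access	flexibility
A	0.62	-0.5	15.0	8.1	0.046	0.007187	1.181	0.357
C	0.29	-1.0	47.0	5.5	0.128	-0.036610	1.461	0.346
D	-0.90	3.0	59.0	13.0	0.105	-0.023820	1.587	0.511
E	-0.74	3.0	73.0	12.3	0.151	0.006802	1.862	0.497
F	1.19	-2.5	91.0	5.2	0.290	0.037552	2.228	0.314
G	0.48	0.0	1.0	9.0	0.000	0.179052	0.881	0.544
H	-0.40	-0.5	82.0	10.4	0.230	-0.010690	2.025	0.323
I	1.38	-1.8	57.0	5.2	0.186	0.021631	1.810	0.462
K	-1.50	3.0	73.0	11.3	0.219	0.017708	2.258	0.466
L	1.06	-1.8	57.0	4.9	0.186	0.051672	1.931	0.365
M	0.64	-1.3	75.0	5.7	0.221	0.002683	2.034	0.295
N	-0.78	0.2	58.0	11.6	0.134	0.005392	1.655	0.463
P	0.12	0.0	42.0	8.0	0.131	0.239531	1.468	0.509
Q	-0.85	0.2	72.0	10.5	0.180	0.049211	1.932	0.493
R	-2.53	3.0	101.0	10.5	0.291	0.043587	2.560	0.529
S	-0.18	0.3	31.0	9.2	0.062	0.004627	1.298	0.507
T	-0.05	-0.4	45.0	8.6	0.108	0.003352	1.525	0.444
V	1.08	-1.5	43.0	5.9	0.140	0.057004	1.645	0.386
W	0.81	-3.4	130.0	5.4	0.409	0.037977	2.663	0.305
Y	0.26	-2.3	107.0	6.2	0.298	0.023599	2.368	0.420
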