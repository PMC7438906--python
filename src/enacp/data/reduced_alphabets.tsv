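# Reduced amino-acid alphabets for the Distance-Pair encoder.
# Groupings follow the physicochemical clustering convention used by
# distance-pair descriptors (hydrophobic, aromatic, polar, charged blocks);
# they are this package's bundled defaults and can be replaced by any
# user-supplied mapping. Clusters are dash-separated; letters within a
# cluster share one symbol class.
name	m	clusters
cp13	13	MF-IL-V-A-C-WYQHP-G-T-S-N-RK-D-E
cp14	14	IMV-L-F-WY-G-P-C-A-S-T-N-HQ-RK-DE
cp19	19	A-C-D-E-F-G-H-IV-K-L-M-N-P-Q-R-S-T-W-Y
cp20	20	A-C-D-E-F-G-H-I-K-L-M-N-P-Q-R-S-T-V-W-Y
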