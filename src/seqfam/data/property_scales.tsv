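property_name	amino_acid	value
hydrophobicity_kd	A	1.8
hydrophobicity_kd	R	-4.5
hydrophobicity_kd	N	-3.5
hydrophobicity_kd	D	-3.5
hydrophobicity_kd	C	2.5
hydrophobicity_kd	Q	-3.5
hydrophobicity_kd	E	-3.5
hydrophobicity_kd	G	-0.4
hydrophobicity_kd	H	-3.2
hydrophobicity_kd	I	4.5
hydrophobicity_kd	L	3.8
hydrophobicity_kd	K	-3.9
hydrophobicity_kd	M	1.9
hydrophobicity_kd	F	2.8
hydrophobicity_kd	P	-1.6
hydrophobicity_kd	S	-0.8
hydrophobicity_kd	T	-0.7
hydrophobicity_kd	W	-0.9
hydrophobicity_kd	Y	-1.3
hydrophobicity_kd	V	4.2
hydrophilicity_hw	A	-0.5
hydrophilicity_hw	R	3.0
hydrophilicity_hw	N	0.2
hydrophilicity_hw	D	3.0
hydrophilicity_hw	C	-1.0
hydrophilicity_hw	Q	0.2
hydrophilicity_hw	E	3.0
hydrophilicity_hw	G	0.0
hydrophilicity_hw	H	-0.5
hydrophilicity_hw	I	-1.8
hydrophilicity_hw	L	-1.8
hydrophilicity_hw	K	3.0
hydrophilicity_hw	M	-1.3
hydrophilicity_hw	F	-2.5
hydrophilicity_hw	P	0.0
hydrophilicity_hw	S	0.3
hydrophilicity_hw	T	-0.4
hydrophilicity_hw	W	-3.4
hydrophilicity_hw	Y	-2.3
hydrophilicity_hw	V	-1.5
residue_mass	A	71.08
residue_mass	R	156.19
residue_mass	N	114.10
residue_mass	D	115.09
residue_mass	C	103.14
residue_mass	Q	128.13
residue_mass	E	129.12
residue_mass	G	57.05
residue_mass	H	137.14
residue_mass	I	113.16
residue_mass	L	113.16
residue_mass	K	128.17
residue_mass	M	131.19
residue_mass	F	147.18
residue_mass	P	97.12
residue_mass	S	87.08
residue_mass	T	101.10
residue_mass	W	186.21
residue_mass	Y	163.18
residue_mass	V	99.13
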