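property_name	amino_acid	class_index
polarity	L	1
polarity	I	1
polarity	F	1
polarity	W	1
polarity	C	1
polarity	M	1
polarity	V	1
polarity	Y	1
polarity	P	2
polarity	A	2
polarity	T	2
polarity	G	2
polarity	S	2
polarity	H	3
polarity	Q	3
polarity	R	3
polarity	K	3
polarity	N	3
polarity	E	3
polarity	D	3
hydrophobicity	R	1
hydrophobicity	K	1
hydrophobicity	E	1
hydrophobicity	D	1
hydrophobicity	Q	1
hydrophobicity	N	1
hydrophobicity	G	2
hydrophobicity	A	2
hydrophobicity	S	2
hydrophobicity	T	2
hydrophobicity	P	2
hydrophobicity	H	2
hydrophobicity	Y	2
hydrophobicity	C	3
hydrophobicity	L	3
hydrophobicity	V	3
hydrophobicity	I	3
hydrophobicity	M	3
hydrophobicity	F	3
hydrophobicity	W	3
surface_tension	G	1
surface_tension	Q	1
surface_tension	D	1
surface_tension	N	1
surface_tension	A	1
surface_tension	H	1
surface_tension	R	1
surface_tension	K	2
surface_tension	T	2
surface_tension	S	2
surface_tension	E	2
surface_tension	C	2
surface_tension	I	3
surface_tension	L	3
surface_tension	M	3
surface_tension	F	3
surface_tension	P	3
surface_tension	W	3
surface_tension	Y	3
surface_tension	V	3
charge	K	1
charge	R	1
charge	A	2
charge	N	2
charge	C	2
charge	Q	2
charge	G	2
charge	H	2
charge	I	2
charge	L	2
charge	M	2
charge	F	2
charge	P	2
charge	S	2
charge	T	2
charge	W	2
charge	Y	2
charge	V	2
charge	D	3
charge	E	3
normalized_vdw_volume	G	1
normalized_vdw_volume	A	1
normalized_vdw_volume	S	1
normalized_vdw_volume	C	1
normalized_vdw_volume	T	1
normalized_vdw_volume	P	1
normalized_vdw_volume	D	1
normalized_vdw_volume	N	2
normalized_vdw_volume	V	2
normalized_vdw_volume	E	2
normalized_vdw_volume	Q	2
normalized_vdw_volume	I	2
normalized_vdw_volume	L	2
normalized_vdw_volume	M	3
normalized_vdw_volume	H	3
normalized_vdw_volume	K	3
normalized_vdw_volume	F	3
normalized_vdw_volume	R	3
normalized_vdw_volume	Y	3
normalized_vdw_volume	W	3
polarizability	G	1
polarizability	A	1
polarizability	S	1
polarizability	D	1
polarizability	T	1
polarizability	C	2
polarizability	P	2
polarizability	N	2
polarizability	V	2
polarizability	E	2
polarizability	Q	2
polarizability	I	2
polarizability	L	2
polarizability	K	3
polarizability	M	3
polarizability	H	3
polarizability	F	3
polarizability	R	3
polarizability	Y	3
polarizability	W	3
secondary_structure	E	1
secondary_structure	A	1
secondary_structure	L	1
secondary_structure	M	1
secondary_structure	Q	1
secondary_structure	K	1
secondary_structure	R	1
secondary_structure	H	1
secondary_structure	V	2
secondary_structure	I	2
secondary_structure	Y	2
secondary_structure	C	2
secondary_structure	W	2
secondary_structure	F	2
secondary_structure	T	2
secondary_structure	G	3
secondary_structure	N	3
secondary_structure	P	3
secondary_structure	S	3
secondary_structure	D	3
solvent_accessibility	A	1
solvent_accessibility	L	1
solvent_accessibility	F	1
solvent_accessibility	C	1
solvent_accessibility	G	1
solvent_accessibility	I	1
solvent_accessibility	V	1
solvent_accessibility	W	1
solvent_accessibility	R	2
solvent_accessibility	K	2
solvent_accessibility	Q	2
solvent_accessibility	E	2
solvent_accessibility	N	2
solvent_accessibility	D	2
solvent_accessibility	M	3
solvent_accessibility	S	3
solvent_accessibility	P	3
solvent_accessibility	T	3
solvent_accessibility	H	3
solvent_accessibility	Y	3
molecular_weight	G	1
molecular_weight	A	1
molecular_weight	S	1
molecular_weight	P	1
molecular_weight	V	1
molecular_weight	T	1
molecular_weight	C	1
molecular_weight	L	2
molecular_weight	I	2
molecular_weight	N	2
molecular_weight	D	2
molecular_weight	Q	2
molecular_weight	K	2
molecular_weight	E	2
molecular_weight	M	3
molecular_weight	H	3
molecular_weight	F	3
molecular_weight	R	3
molecular_weight	Y	3
molecular_weight	W	3
solubility	P	1
solubility	K	1
solubility	G	1
solubility	R	1
solubility	A	1
solubility	C	1
solubility	T	1
solubility	V	2
solubility	S	2
solubility	H	2
solubility	I	2
solubility	N	2
solubility	M	2
solubility	F	2
solubility	Q	3
solubility	L	3
solubility	W	3
solubility	E	3
solubility	D	3
solubility	Y	3
hbond_donors	A	1
hbond_donors	G	1
hbond_donors	I	1
hbond_donors	L	1
hbond_donors	M	1
hbond_donors	F	1
hbond_donors	P	1
hbond_donors	V	1
hbond_donors	C	2
hbond_donors	D	2
hbond_donors	E	2
hbond_donors	S	2
hbond_donors	T	2
hbond_donors	W	2
hbond_donors	Y	2
hbond_donors	H	2
hbond_donors	R	3
hbond_donors	N	3
hbond_donors	Q	3
hbond_donors	K	3
hbond_acceptors	A	1
hbond_acceptors	C	1
hbond_acceptors	F	1
hbond_acceptors	G	1
hbond_acceptors	I	1
hbond_acceptors	L	1
hbond_acceptors	M	1
hbond_acceptors	P	1
hbond_acceptors	V	1
hbond_acceptors	W	1
hbond_acceptors	S	2
hbond_acceptors	T	2
hbond_acceptors	Y	2
hbond_acceptors	H	2
hbond_acceptors	K	2
hbond_acceptors	N	2
hbond_acceptors	Q	2
hbond_acceptors	D	3
hbond_acceptors	E	3
hbond_acceptors	R	3
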