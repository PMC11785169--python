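# rTRPM3 apo (no ligand), vitrified at 18 C.
# Transcribed published final per-class particle counts from the
# symmetry-expanded per-subunit classification of this dataset
# (intact tetramers only; rotation classes of R/A subunit states).
class_name,count
4R0A,1138501
3R1A,762853
2R2A_ortho,187643
2R2A_para,62369
1R3A,37679
0R4A,2822
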