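# rTRPM3 apo (no ligand), vitrified at 37 C (heat condition).
# Transcribed published final per-class particle counts from the
# symmetry-expanded per-subunit classification of this dataset
# (intact tetramers only; rotation classes of R/A subunit states).
class_name,count
4R0A,111874
3R1A,125354
2R2A_ortho,84256
2R2A_para,30726
1R3A,84811
0R4A,40005
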