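# rTRPM3 + CIM0216 (superagonist), vitrified at 18 C.
# Transcribed published final per-class particle counts from the
# symmetry-expanded per-subunit classification of this dataset
# (intact tetramers only; rotation classes of R/A subunit states).
class_name,count
4R0A,1642
3R1A,29177
2R2A_ortho,127753
2R2A_para,81343
1R3A,577875
0R4A,563237
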