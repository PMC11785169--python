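# rTRPM3 + primidone (antagonist), vitrified at 18 C.
# Transcribed published final per-class particle counts from the
# symmetry-expanded per-subunit classification of this dataset
# (intact tetramers only; rotation classes of R/A subunit states).
class_name,count
4R0A,419231
3R1A,415433
2R2A_ortho,213123
2R2A_para,56912
1R3A,122730
0R4A,43855
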