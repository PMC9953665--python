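>preproinsulin_human canonical 110-aa precursor (UniProt P01308); signal 1-24, B 25-54, RR 55-56, C 57-87, KR 88-89, A 90-110
MALWMRLLPLLALLALWGPDPAAAFVNQHLCGSHLVEALYLVCGERGFFYTPKTRREAED
LQVGQVELGGGPGAGSLQPLALEGSLQKRGIVEQCCTSICSLYQLENYCN
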