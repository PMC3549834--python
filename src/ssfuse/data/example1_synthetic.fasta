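>1G6X_A synthetic stand-in: 58 residues, cysteines at 5,14,31,38,51,55
PYIICKWVPHKRNCSFNLQPFHYPTPYQPQCMMSWPFCVKEDKMLGSDQACLPKCYWI
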