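>benchmark_ref synthetic stand-in: random catalytic-domain-sized core with flanking structure cassettes
GGCCTTCGGGCCAAAGCAAATGTATTGTACGATATAGTCGGCGTGGAAGCTTGTTTCTTT
TGCGCGCCGAGATGCGATGCGCATGATGTAGGGCAACGTCGACTGGCAGCCTGCGCTAAA
GAGTTGAGTCAGTTATTGAATGGGGAAGGCAGTGAGAATGAACTCTACTGGTTGCGAGCC
TGCTATAGTCTTGTCCGCCACTCGCCTTGGATTAAGTGATTACGTAAGTTATGAGTACAA
CATTTCCCTGGTTAAGGCGGCAGCAGTGGGCTCTCGGCCTCATCGATCCGGTTCGCCGGA
TCCAAATCGGGCTTCGGTCCGGTTC
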