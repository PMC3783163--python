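>attP synthetic crossover=24,25
TTTAGTATCTGGTTTTAGAACGATGCAGCGATCCAAAACCAGATACTAAA
>attB synthetic crossover=19,20
TTTAGTATCTTAGAACGATGCAGCGATCCAAGATACTAAA
>attL synthetic crossover=24,25
TTTAGTATCTGGTTTTAGAACGATGCAGCGATCCAAGATACTAAA
>attR synthetic crossover=19,20
TTTAGTATCTTAGAACGATGCAGCGATCCAAAACCAGATACTAAA
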