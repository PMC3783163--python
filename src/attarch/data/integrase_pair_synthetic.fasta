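>integrase_ref synthetic 452 aa
MPVYHRDTLCSITRQYAVTAEMPDCVPHMRSYLHDAYRGSASTTQRAKVICYSYTHCAKTNPGKKSTSYWYRRFTGKCPWQPYKGRKEPIWPRTMLKGNPFIKECPATNDHDYDKDVMPKLAEMDCRKHHDEAIYTKWHDCMKKVVAHDRNDWWFSQWVTWKMTNSDWHHGIKHHPEFIKYVQWEHPLPNHDAHSPGMLVWKLCPVILAAPVMTCCDGKSSIFELNDLTTADFVIFKPCYQFKQSLVQDHTPPWPFYILQNKYYINYNLHQVYCQCCSYNSHVFRRPKQYRMDYWNMLQILCEDGKKLNGLMMCGPCSPWCKTSKTDVQLMADHATEAHRRAWMWAQVAQWSTYADNFDEGWLGRGTMLQMDAYIIFRLNFKMKTPEREQDKVYLAGAQQAQKKKYLRGTYAKYQKYITKKQYDNNNSMMRRGMNVQTLVLMQFDEFKSGID
>integrase_homolog synthetic 11 conservative differences at 140,171,205,233,258,281,329,355,390,421,440
MPVYHRDTLCSITRQYAVTAEMPDCVPHMRSYLHDAYRGSASTTQRAKVICYSYTHCAKTNPGKKSTSYWYRRFTGKCPWQPYKGRKEPIWPRTMLKGNPFIKECPATNDHDYDKDVMPKLAEMDCRKHHDEAIYTKWHECMKKVVAHDRNDWWFSQWVTWKMTNSDWHHAIKHHPEFIKYVQWEHPLPNHDAHSPGMLVWKLCAVILAAPVMTCCDGKSSIFELNDLTTADYVIFKPCYQFKQSLVQDHTPPWPFYLLQNKYYINYNLHQVYCQCCSYNTHVFRRPKQYRMDYWNMLQILCEDGKKLNGLMMCGPCSPWCKTSKTDVNLMADHATEAHRRAWMWAQVAQWSTYSDNFDEGWLGRGTMLQMDAYIIFRLNFKMKTPERENDKVYLAGAQQAQKKKYLRGTYAKYQKYITKRQYDNNNSMMRRGMNVQTLILMQFDEFKSGID
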