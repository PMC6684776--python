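>aM1 astratide, Radix Astragali, PA1b-like, 37 aa
VDCSGACSPFEVPPCGSRDCRCIPIGLVVGFCIYPTG
>bM1 astratide, Radix Astragali, defensin, 45 aa
CEKPSKFFSGPCIGSSGKTQCAYLCRRGEGLQDGNCKGLKCVCAC
>hP1 hedytide, Radix Hedysarum, PA1b-like, 37 aa
QGCNGPCTPFEQPPCGIQSCRCFPEVLFFGRCSTPSG
>hP2 hedytide, Radix Hedysarum, defensin, 45 aa
CEKGSEFFVGACRYSEGTQQCATLCSRGEGLQGGKCKGVRCYCSC
>aB1 achyranthes, Achyranthes bidentata, six-cysteine hevein-like, 33 aa
CLESGTSCIPGAPHDCCSGVCIPIVTVFYGKCY
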