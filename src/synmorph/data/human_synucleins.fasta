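>NM_000345.4 Homo sapiens alpha-synuclein, CDS protein product (UniProt P37840)
MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK
EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP
DNEAYEMPSEEGYQDYEPEA
>NM_001001502.3 Homo sapiens beta-synuclein, CDS protein product (UniProt Q16143)
MDVFMKGLSMAKEGVVAAAEKTKQGVTEAAEKTKEGVLYVGSKTREGVVQGVASVAEKTK
EQASHLGGAVFSGAGNIAAATGLVKREEFPTDLKPEEVAQEAAEEPLIEPLMEPEGESYE
DPPQEEYQEYEPEA
>NM_003087.3 Homo sapiens gamma-synuclein, CDS protein product (UniProt O76070)
MDVFKKGFSIAKEGVVGAVEKTKQGVTEAAEKTKEGVMYVGAKTKENVVQSVTSVAEKTK
EQANAVSEAVVSSVNTVATKTVEEAENIAVTSGVVRKEDLRPSAPQQEGVASKEKEEVAE
EAQSGGD
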