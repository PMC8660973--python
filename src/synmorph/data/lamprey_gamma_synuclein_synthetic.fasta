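>synthetic_lamprey_gamma_synuclein SYNTHETIC stand-in (random 35% perturbation of human gamma-synuclein, truncated to 115 aa); NOT GenBank JN544525.1
MVVFKYGFSIAKDGVVGAVQKTKQGTQEWATKTKPGVMYQGAKTQGPVDQHVTRVNEKTI
EQKIAVSERVICVVFTAAYKCVEEAENILDTSEIVRKEDLLLPAMQQEHVANHNK
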