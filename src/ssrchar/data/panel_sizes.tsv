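species	n_accessions
Paspalum plicatulum	26
Paspalum atratum	3
Paspalum compressifolium	4
Paspalum guenoarum	6
Paspalum lenticulare	3
Paspalum lepton	1
Paspalum rhodopedum	3
Paspalum rojasii	2
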