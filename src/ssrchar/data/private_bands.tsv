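locus	Paspalum plicatulum	Paspalum atratum	Paspalum compressifolium	Paspalum guenoarum	Paspalum lenticulare	Paspalum lepton	Paspalum rhodopedum	Paspalum rojasii
Pp-UNICAMP01	1	0	0	0	0	0	0	0
Pp-UNICAMP02	1	0	0	0	0	0	0	0
Pp-UNICAMP03	0	0	0	0	0	0	0	0
Pp-UNICAMP04	0	1	0	0	2	0	0	0
Pp-UNICAMP05	0	2	0	1	0	2	0	0
Pp-UNICAMP06	1	0	0	0	0	0	0	0
Pp-UNICAMP07	0	0	0	0	0	0	0	0
Pp-UNICAMP08	1	0	0	0	0	0	0	0
Pp-UNICAMP09	1	0	0	0	0	0	0	0
Pp-UNICAMP10	0	1	1	0	0	0	0	0
Pp-UNICAMP11	0	0	0	0	0	0	1	0
Pp-UNICAMP12	3	2	0	0	0	0	0	0
Pp-UNICAMP13	2	0	0	0	0	0	0	0
Pp-UNICAMP14	0	1	0	1	0	0	0	0
Pp-UNICAMP15	1	0	0	0	0	0	0	0
Pp-UNICAMP16	0	1	0	1	0	0	0	0
Pp-UNICAMP17	5	0	0	0	1	0	1	0
Pp-UNICAMP18	1	0	0	0	3	0	0	0
Pp-UNICAMP19	1	0	0	1	0	0	0	0
Pp-UNICAMP20	0	0	0	0	0	0	0	0
Pp-UNICAMP21	2	2	0	0	0	0	2	0
Pp-UNICAMP22	0	0	0	0	0	0	0	0
Pp-UNICAMP23	0	1	0	0	0	0	0	0
Pp-UNICAMP24	1	0	1	0	0	0	0	0
Pp-UNICAMP25	0	0	0	1	0	0	0	0
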