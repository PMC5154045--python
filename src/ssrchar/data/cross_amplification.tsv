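locus	species	amplified	tested
Pp-UNICAMP01	Paspalum atratum	3	3
Pp-UNICAMP01	Paspalum compressifolium	3	4
Pp-UNICAMP01	Paspalum guenoarum	2	6
Pp-UNICAMP01	Paspalum lenticulare	3	3
Pp-UNICAMP01	Paspalum lepton	0	1
Pp-UNICAMP01	Paspalum rhodopedum	0	3
Pp-UNICAMP01	Paspalum rojasii	0	2
Pp-UNICAMP02	Paspalum atratum	2	3
Pp-UNICAMP02	Paspalum compressifolium	4	4
Pp-UNICAMP02	Paspalum guenoarum	5	6
Pp-UNICAMP02	Paspalum lenticulare	3	3
Pp-UNICAMP02	Paspalum lepton	0	1
Pp-UNICAMP02	Paspalum rhodopedum	2	3
Pp-UNICAMP02	Paspalum rojasii	1	2
Pp-UNICAMP03	Paspalum atratum	2	3
Pp-UNICAMP03	Paspalum compressifolium	3	4
Pp-UNICAMP03	Paspalum guenoarum	5	6
Pp-UNICAMP03	Paspalum lenticulare	3	3
Pp-UNICAMP03	Paspalum lepton	0	1
Pp-UNICAMP03	Paspalum rhodopedum	2	3
Pp-UNICAMP03	Paspalum rojasii	1	2
Pp-UNICAMP04	Paspalum atratum	3	3
Pp-UNICAMP04	Paspalum compressifolium	4	4
Pp-UNICAMP04	Paspalum guenoarum	4	6
Pp-UNICAMP04	Paspalum lenticulare	3	3
Pp-UNICAMP04	Paspalum lepton	1	1
Pp-UNICAMP04	Paspalum rhodopedum	2	3
Pp-UNICAMP04	Paspalum rojasii	1	2
Pp-UNICAMP05	Paspalum atratum	2	3
Pp-UNICAMP05	Paspalum compressifolium	3	4
Pp-UNICAMP05	Paspalum guenoarum	1	6
Pp-UNICAMP05	Paspalum lenticulare	0	3
Pp-UNICAMP05	Paspalum lepton	0	1
Pp-UNICAMP05	Paspalum rhodopedum	0	3
Pp-UNICAMP05	Paspalum rojasii	0	2
Pp-UNICAMP06	Paspalum atratum	3	3
Pp-UNICAMP06	Paspalum compressifolium	4	4
Pp-UNICAMP06	Paspalum guenoarum	6	6
Pp-UNICAMP06	Paspalum lenticulare	3	3
Pp-UNICAMP06	Paspalum lepton	1	1
Pp-UNICAMP06	Paspalum rhodopedum	2	3
Pp-UNICAMP06	Paspalum rojasii	2	2
Pp-UNICAMP07	Paspalum atratum	3	3
Pp-UNICAMP07	Paspalum compressifolium	4	4
Pp-UNICAMP07	Paspalum guenoarum	5	6
Pp-UNICAMP07	Paspalum lenticulare	3	3
Pp-UNICAMP07	Paspalum lepton	1	1
Pp-UNICAMP07	Paspalum rhodopedum	3	3
Pp-UNICAMP07	Paspalum rojasii	1	2
Pp-UNICAMP08	Paspalum atratum	3	3
Pp-UNICAMP08	Paspalum compressifolium	4	4
Pp-UNICAMP08	Paspalum guenoarum	6	6
Pp-UNICAMP08	Paspalum lenticulare	3	3
Pp-UNICAMP08	Paspalum lepton	1	1
Pp-UNICAMP08	Paspalum rhodopedum	2	3
Pp-UNICAMP08	Paspalum rojasii	1	2
Pp-UNICAMP09	Paspalum atratum	2	3
Pp-UNICAMP09	Paspalum compressifolium	2	4
Pp-UNICAMP09	Paspalum guenoarum	3	6
Pp-UNICAMP09	Paspalum lenticulare	2	3
Pp-UNICAMP09	Paspalum lepton	0	1
Pp-UNICAMP09	Paspalum rhodopedum	2	3
Pp-UNICAMP09	Paspalum rojasii	1	2
Pp-UNICAMP10	Paspalum atratum	3	3
Pp-UNICAMP10	Paspalum compressifolium	4	4
Pp-UNICAMP10	Paspalum guenoarum	5	6
Pp-UNICAMP10	Paspalum lenticulare	3	3
Pp-UNICAMP10	Paspalum lepton	1	1
Pp-UNICAMP10	Paspalum rhodopedum	3	3
Pp-UNICAMP10	Paspalum rojasii	1	2
Pp-UNICAMP11	Paspalum atratum	3	3
Pp-UNICAMP11	Paspalum compressifolium	4	4
Pp-UNICAMP11	Paspalum guenoarum	5	6
Pp-UNICAMP11	Paspalum lenticulare	3	3
Pp-UNICAMP11	Paspalum lepton	1	1
Pp-UNICAMP11	Paspalum rhodopedum	3	3
Pp-UNICAMP11	Paspalum rojasii	1	2
Pp-UNICAMP12	Paspalum atratum	2	3
Pp-UNICAMP12	Paspalum compressifolium	4	4
Pp-UNICAMP12	Paspalum guenoarum	5	6
Pp-UNICAMP12	Paspalum lenticulare	3	3
Pp-UNICAMP12	Paspalum lepton	0	1
Pp-UNICAMP12	Paspalum rhodopedum	1	3
Pp-UNICAMP12	Paspalum rojasii	1	2
Pp-UNICAMP13	Paspalum atratum	3	3
Pp-UNICAMP13	Paspalum compressifolium	4	4
Pp-UNICAMP13	Paspalum guenoarum	5	6
Pp-UNICAMP13	Paspalum lenticulare	3	3
Pp-UNICAMP13	Paspalum lepton	1	1
Pp-UNICAMP13	Paspalum rhodopedum	3	3
Pp-UNICAMP13	Paspalum rojasii	2	2
Pp-UNICAMP14	Paspalum atratum	3	3
Pp-UNICAMP14	Paspalum compressifolium	4	4
Pp-UNICAMP14	Paspalum guenoarum	5	6
Pp-UNICAMP14	Paspalum lenticulare	3	3
Pp-UNICAMP14	Paspalum lepton	1	1
Pp-UNICAMP14	Paspalum rhodopedum	1	3
Pp-UNICAMP14	Paspalum rojasii	2	2
Pp-UNICAMP15	Paspalum atratum	2	3
Pp-UNICAMP15	Paspalum compressifolium	4	4
Pp-UNICAMP15	Paspalum guenoarum	5	6
Pp-UNICAMP15	Paspalum lenticulare	2	3
Pp-UNICAMP15	Paspalum lepton	0	1
Pp-UNICAMP15	Paspalum rhodopedum	2	3
Pp-UNICAMP15	Paspalum rojasii	2	2
Pp-UNICAMP16	Paspalum atratum	2	3
Pp-UNICAMP16	Paspalum compressifolium	4	4
Pp-UNICAMP16	Paspalum guenoarum	4	6
Pp-UNICAMP16	Paspalum lenticulare	2	3
Pp-UNICAMP16	Paspalum lepton	0	1
Pp-UNICAMP16	Paspalum rhodopedum	2	3
Pp-UNICAMP16	Paspalum rojasii	1	2
Pp-UNICAMP17	Paspalum atratum	3	3
Pp-UNICAMP17	Paspalum compressifolium	4	4
Pp-UNICAMP17	Paspalum guenoarum	6	6
Pp-UNICAMP17	Paspalum lenticulare	2	3
Pp-UNICAMP17	Paspalum lepton	1	1
Pp-UNICAMP17	Paspalum rhodopedum	2	3
Pp-UNICAMP17	Paspalum rojasii	2	2
Pp-UNICAMP18	Paspalum atratum	2	3
Pp-UNICAMP18	Paspalum compressifolium	1	4
Pp-UNICAMP18	Paspalum guenoarum	5	6
Pp-UNICAMP18	Paspalum lenticulare	3	3
Pp-UNICAMP18	Paspalum lepton	0	1
Pp-UNICAMP18	Paspalum rhodopedum	3	3
Pp-UNICAMP18	Paspalum rojasii	1	2
Pp-UNICAMP19	Paspalum atratum	3	3
Pp-UNICAMP19	Paspalum compressifolium	4	4
Pp-UNICAMP19	Paspalum guenoarum	4	6
Pp-UNICAMP19	Paspalum lenticulare	3	3
Pp-UNICAMP19	Paspalum lepton	1	1
Pp-UNICAMP19	Paspalum rhodopedum	3	3
Pp-UNICAMP19	Paspalum rojasii	1	2
Pp-UNICAMP20	Paspalum atratum	3	3
Pp-UNICAMP20	Paspalum compressifolium	4	4
Pp-UNICAMP20	Paspalum guenoarum	1	6
Pp-UNICAMP20	Paspalum lenticulare	3	3
Pp-UNICAMP20	Paspalum lepton	1	1
Pp-UNICAMP20	Paspalum rhodopedum	0	3
Pp-UNICAMP20	Paspalum rojasii	0	2
Pp-UNICAMP21	Paspalum atratum	3	3
Pp-UNICAMP21	Paspalum compressifolium	4	4
Pp-UNICAMP21	Paspalum guenoarum	4	6
Pp-UNICAMP21	Paspalum lenticulare	2	3
Pp-UNICAMP21	Paspalum lepton	1	1
Pp-UNICAMP21	Paspalum rhodopedum	2	3
Pp-UNICAMP21	Paspalum rojasii	1	2
Pp-UNICAMP22	Paspalum atratum	3	3
Pp-UNICAMP22	Paspalum compressifolium	4	4
Pp-UNICAMP22	Paspalum guenoarum	3	6
Pp-UNICAMP22	Paspalum lenticulare	1	3
Pp-UNICAMP22	Paspalum lepton	1	1
Pp-UNICAMP22	Paspalum rhodopedum	1	3
Pp-UNICAMP22	Paspalum rojasii	1	2
Pp-UNICAMP23	Paspalum atratum	3	3
Pp-UNICAMP23	Paspalum compressifolium	1	4
Pp-UNICAMP23	Paspalum guenoarum	6	6
Pp-UNICAMP23	Paspalum lenticulare	1	3
Pp-UNICAMP23	Paspalum lepton	1	1
Pp-UNICAMP23	Paspalum rhodopedum	1	3
Pp-UNICAMP23	Paspalum rojasii	0	2
Pp-UNICAMP24	Paspalum atratum	3	3
Pp-UNICAMP24	Paspalum compressifolium	4	4
Pp-UNICAMP24	Paspalum guenoarum	5	6
Pp-UNICAMP24	Paspalum lenticulare	2	3
Pp-UNICAMP24	Paspalum lepton	1	1
Pp-UNICAMP24	Paspalum rhodopedum	2	3
Pp-UNICAMP24	Paspalum rojasii	2	2
Pp-UNICAMP25	Paspalum atratum	3	3
Pp-UNICAMP25	Paspalum compressifolium	1	4
Pp-UNICAMP25	Paspalum guenoarum	5	6
Pp-UNICAMP25	Paspalum lenticulare	1	3
Pp-UNICAMP25	Paspalum lepton	1	1
Pp-UNICAMP25	Paspalum rhodopedum	1	3
Pp-UNICAMP25	Paspalum rojasii	1	2
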