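# Kinase consensus motifs in linear notation anchored at the phospho-acceptor.
# Only the CK2 consensus (acidic +3) is central to the default analysis; the
# other entries are literature-standard defaults and should be replaced where
# exact group membership matters.
kinase	pattern	description
Akt	R-X-R-X-X-(S/T)	basophilic RxRxxS/T
AMPK	(L/M)-X-R-X-X-(S/T)	hydrophobic-basic context
Aurora	(R/K)-X-(S/T)	basic at -2
CaMK2	R-X-X-(S/T)	basic at -3
Cdc2	(S/T)-P-X-X-(K/R)	proline-directed, basic at +4
CDK1	(S/T)-P-X-(K/R)	proline-directed, basic at +3
CK1	(D/E)-(D/E)-X-X-(S/T)	acidic upstream
CK2	X-(S/T)-X-X-(D/E)	acidic at +3
ERK/MAPK	P-X-(S/T)-P	proline at -2 and +1
GSK3	(S/T)*-X-X-X-(S/T)	primed S/T at +4
PKA	R-(R/K)-X-(S/T)	basic at -3/-2
S6K	(K/R)-X-(K/R)-X-X-(S/T)	basophilic
TOR	(F/L)-X-X-(S/T)	hydrophobic at -3
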