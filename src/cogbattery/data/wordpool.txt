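boter
brood
kaas
appel
stoel
tafel
raam
deur
fiets
bloem
water
vuur
berg
rivier
schip
trein
paard
hond
kat
vogel
boom
gras
steen
zand
wolk
regen
zon
maan
ster
boek
pen
krant
brief
klok
schoen
jas
hoed
mes
vork
lepel
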