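# Fast-food chain names, one per line, pre-normalized (lowercase, no punctuation).
# An entry is fast food when its normalized brand contains one of these as a substring.
mcdonalds
burger king
wendys
taco bell
kfc
kentucky fried chicken
subway
dominos
pizza hut
papa johns
little caesars
chick fil a
chickfila
popeyes
dairy queen
sonic drive in
arbys
jack in the box
chipotle
panda express
whataburger
carls jr
hardees
five guys
in n out
innout
white castle
checkers
raising canes
del taco
wingstop
jimmy johns
culvers
zaxbys
bojangles
long john silvers
church s chicken
churchs chicken
el pollo loco
qdoba
panera
dunkin donuts
krispy kreme
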