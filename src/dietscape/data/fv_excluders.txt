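# Tokens that veto the fruit/vegetable label: juices (excluded by design) and
# processed preparations that are not fresh produce. Whole-token matches.
juice
juices
smoothie
nectar
dried
jam
jelly
preserves
pie
cobbler
cake
muffin
bread
candy
candied
syrup
soda
flavored
chips
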