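# Sugary soda drink names, one per line, pre-normalized.
# An entry is soda when its normalized brand contains one of these as a substring
# and the description contains no excluder token (diet/lite/light/zero).
coca cola
cocacola
coke
pepsi
sprite
fanta
mountain dew
mtn dew
dr pepper
7 up
7up
root beer
barqs
mug root beer
crush
sunkist
sierra mist
ginger ale
canada dry
schweppes
mello yello
squirt
big red
cream soda
cherry soda
orange soda
grape soda
rc cola
jarritos
faygo
shasta
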