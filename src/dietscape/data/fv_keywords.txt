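# Fresh fruit and vegetable terms, one per line, pre-normalized.
# SYNTHETIC approximation: the original study used a proprietary keyword
# classifier; this editable list follows USDA MyPlate food-group items
# (juices intentionally excluded via fv_excluders.txt). Matched as whole
# token sequences of the normalized brand or description.
apple
banana
orange
grapefruit
grape
grapes
strawberry
strawberries
blueberry
blueberries
raspberry
raspberries
blackberry
blackberries
cantaloupe
honeydew
watermelon
melon
peach
nectarine
pear
plum
apricot
cherries
mango
pineapple
kiwi
pomegranate
fig
date fruit
avocado
spinach
kale
arugula
lettuce
romaine
salad
carrot
carrots
broccoli
cauliflower
tomato
tomatoes
cucumber
bell pepper
onion
onions
celery
zucchini
squash
butternut squash
sweet potato
green beans
snap peas
peas
edamame
corn on the cob
cabbage
bok choy
beets
radish
asparagus
brussels sprouts
mushroom
mushrooms
eggplant
okra
artichoke
leek
turnip
parsnip
collard greens
swiss chard
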