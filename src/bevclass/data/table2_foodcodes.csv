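code,cycle,main_description,additional_description,wweia_category,kcal_per_100g,grams_per_floz
92550030,2013-2016-combined,"Fruit juice drink, with high vitamin C, light",,7204,19.1667,30.0
92550035,2013-2016-combined,"Fruit juice drink, light",,7204,39.1667,30.0
92550040,2013-2016-combined,"Fruit juice drink, diet",,7204,19.1667,30.0
92550110,2013-2016-combined,"Cranberry juice drink, with high vitamin C, light",,7204,19.1667,30.0
92550200,2013-2016-combined,"Grape juice drink, light",,7204,20.8334,30.0
92550350,2013-2016-combined,"Orange juice beverage, 40-50% juice, light",,7204,20.8334,30.0
92550360,2013-2016-combined,"Apple juice beverage, 40-50% juice, light",,7204,22.9167,30.0
92550370,2013-2016-combined,"Lemonade, fruit juice drink, light",,7204,21.6667,30.0
92550380,2013-2016-combined,"Pomegranate juice beverage, 40-50% juice, light",,7204,54.1667,30.0
92550400,2013-2016-combined,"Vegetable and fruit juice drink, with high vitamin C, diet",,7106,4.1667,30.0
92550405,2013-2016-combined,"Vegetable and fruit juice drink, with high vitamin C, light",,7204,4.1667,30.0
92550610,2013-2016-combined,"Fruit flavored drink, with high vitamin C, diet",,7106,2.0833,30.0
92550620,2013-2016-combined,"Fruit flavored drink, diet",,7106,4.1667,30.0
92552000,2013-2016-combined,"Fruit flavored drink, with high vitamin C, powdered, reconstituted, diet",,7106,2.0833,30.0
92552010,2013-2016-combined,"Fruit flavored drink, powdered, reconstituted, diet",,7106,2.0833,30.0
92552020,2013-2016-combined,"Sunny D, reduced sugar",,7204,2.0833,30.0
92552030,2013-2016-combined,"Capri Sun, fruit juice drink",,7204,40.4167,30.0
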