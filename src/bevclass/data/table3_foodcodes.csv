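code,cycle,main_description,additional_description,wweia_category,kcal_per_100g,grams_per_floz
92530610,2013-2016-combined,"Fruit juice drink, with high Vitamin C",,7204,47.5,30.0
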