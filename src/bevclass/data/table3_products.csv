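brand,code,cycle,ingredients,kcal_per_8floz_mfr,ingredients_known
Apple and Eve juice drinks,92530610,2013-2016-combined,water; sugar,110,True
Florida's Naturals juice cocktails,92530610,2013-2016-combined,water; sugar,130,True
Hawaiian Punch Green Berry Rush,92530610,2013-2016-combined,water; high fructose corn syrup; sucralose; acek,60,True
Hawaiian Punch Fruit Juicy Red,92530610,2013-2016-combined,water; high fructose corn syrup; sucralose,60,True
Hi-C,92530610,2013-2016-combined,water; high fructose corn syrup,110,True
Kool-Aid Jammers,92530610,2013-2016-combined,water; sugar; sucralose,30,True
Minute Maid small bottles and cans,92530610,2013-2016-combined,water; high fructose corn syrup,110,True
Minute Maid large bottles and cans,92530610,2013-2016-combined,water; high fructose corn syrup; sucralose,90,True
Minute Maid Coolers,92530610,2013-2016-combined,water; high fructose corn syrup,120,True
Ocean Spray juice drink or cocktail flavors other than cranberry,92530610,2013-2016-combined,water; sugar,110,True
Ssips,92530610,2013-2016-combined,water; high fructose corn syrup,120,True
Tropicana fruit punch,92530610,2013-2016-combined,water; sugar,130,True
Tropicana Lemonade chilled carton,92530610,2013-2016-combined,water; sugar,120,True
Tropicana Twister all flavors except lemonade,92530610,2013-2016-combined,water; sugar,140,True
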