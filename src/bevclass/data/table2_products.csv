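brand,code,cycle,ingredients,kcal_per_8floz_mfr,ingredients_known
Light Hawaiian Punch,92550030,2013-2016-combined,water; sucralose; acek,10,True
Minute Maid Light juice drinks,92550030,2013-2016-combined,water; aspartame; acek,15,True
Tropicana Light lemonade,92550030,2013-2016-combined,water; sucralose,10,True
Minute Maid Light fruit punch,92550035,2013-2016-combined,water; aspartame; acek,15,True
Sunsweet prune juice light,92550035,2013-2016-combined,water; sugar; sucralose,100,True
Plumsmart Light plum juice,92550035,2013-2016-combined,water; sugar; sucralose,60,True
Diet Snapple juice drinks,92550040,2013-2016-combined,water; aspartame,10,True
Ocean Spray Light Cranberry Juice Cocktail,92550110,2013-2016-combined,water; sugar; sucralose,50,True
Apple and Eve Light Cranberry juice drinks,92550110,2013-2016-combined,water; sucralose; acek,10,True
Welch's Light juice drinks,92550200,2013-2016-combined,water; sugar; sucralose; acek,45,True
Tropicana Trop 50,92550350,2013-2016-combined,water; sugar; reba,50,True
Minute Maid Light,92550350,2013-2016-combined,water; sugar; sucralose; acek,50,True
Dole Light,92550350,2013-2016-combined,,,False
Tropicana Trop 50 apple,92550360,2013-2016-combined,water; sugar; reba,50,True
Mott's Light,92550360,2013-2016-combined,water; sugar; sucralose,50,True
Tropicana Trop 50 Lemonade,92550370,2013-2016-combined,water; sugar; reba,50,True
POM Lite all flavors,92550380,2013-2016-combined,water; sugar,75,True
Diet V8 Splash all flavors low calorie,92550400,2013-2016-combined,water; sucralose; acek,10,True
V8 V-Fusion Light all flavors,92550405,2013-2016-combined,water; sugar; sucralose,50,True
Diet Ocean Spray cranberry blueberry or pomegranate blends,92550610,2013-2016-combined,water; acek; sucralose,5,True
Crystal Light,92550620,2013-2016-combined,water; sucralose; acek,5,True
Minute Maid Light,92550620,2013-2016-combined,water; aspartame; acek,15,True
Sugar Free Tang On-the-Go,92552000,2013-2016-combined,water; aspartame; acek,5,True
Country Time Lite lemonade,92552000,2013-2016-combined,water; sugar; sucralose; acek; neotame,35,True
Ocean Spray drink mix low calorie,92552000,2013-2016-combined,water; aspartame; acek,5,True
Crystal Light,92552010,2013-2016-combined,water; aspartame; acek; rebiana,5,True
Sugar Free Kool-Aid,92552010,2013-2016-combined,water; aspartame; acek,5,True
Wyler's Light,92552010,2013-2016-combined,water; aspartame; acek,5,True
Reduced Sugar Sunny Delight fruit juice drink all flavors,92552020,2013-2016-combined,water; high fructose corn syrup; sucralose; acek; neotame,60,True
Capri Sun NFS 25% less sugar,92552030,2013-2016-combined,water; high fructose corn syrup,94,True
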