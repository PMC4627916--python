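product_id,name,category,energy_kcal,protein_g,carbohydrate_g,sugar_g,fat_g,sfa_g,mufa_g,pufa_g,fiber_g,pooled_weight
gf01,Flour,flour/bake mix,345.5,3.7,77.6,1.0,1.7,0.2,0.3,1.0,3.8,2
gf02,Bake mix white (cake),flour/bake mix,338.4,3.2,77.5,17.8,1.2,0.3,0.5,0.5,2.3,1
gf03,Bake mix brown (cake),flour/bake mix,394.7,2.6,82.9,52.5,5.4,3.1,1.8,0.4,2.8,1
gf04,Bake mix (Pizza),flour/bake mix,322.7,5.9,70.3,1.5,1.9,0.4,0.8,0.7,3.9,2
gf05,Breadcrumbs,flour/bake mix,350.8,5.9,70.1,0.4,4.8,1.3,1.9,1.2,6.0,2
gf06,Rustic bread,bread/bakery,238.4,3.7,51.0,0.7,1.9,0.3,0.8,0.6,1.4,1
gf07,Whole-grain bread,bread/bakery,263.6,8.5,40.8,5.1,7.2,1.0,2.2,3.9,8.4,1
gf08,Toast,bread/bakery,224.8,4.8,39.0,2.1,5.3,1.4,2.0,1.5,6.3,2
gf09,Bun,bread/bakery,259.2,1.4,48.7,5.2,6.2,3.0,1.6,1.2,1.6,1
gf10,Ciabatta,bread/bakery,213.4,3.3,44.9,2.9,2.0,0.3,2.3,0.7,8.3,1
gf11,Raisin bread,bread/bakery,261.0,4.0,49.1,18.6,4.2,1.5,0.8,0.8,1.6,1
gf12,Scone,bread/bakery,293.2,3.7,52.2,13.8,7.5,2.2,1.4,1.1,2.7,1
gf13,Baguette,bread/bakery,270.1,4.5,56.7,6.4,2.5,0.4,1.9,3.0,5.3,1
gf14,Lye Pretzel,bread/bakery,343.8,4.8,59.2,7.8,9.4,4.7,1.0,0.9,2.2,1
gf15,Rusk,bread/bakery,343.9,0.3,82.5,0.8,0.9,0.3,3.2,0.7,0.7,1
gf16,Crispbread,bread/bakery,351.6,6.9,77.8,6.0,0.9,0.2,0.4,0.2,2.9,1
gf17,Wraps,bread/bakery,228.7,3.1,38.8,0.4,7.5,2.2,0.3,0.4,2.8,1
gf18,Fusilli,pasta/cereal-based,335.9,8.2,69.9,1.0,2.2,0.3,0.7,1.1,7.2,1
gf19,Spaghetti,pasta/cereal-based,329.0,8.7,66.3,1.3,2.8,0.4,0.9,1.4,9.4,1
gf20,Penne,pasta/cereal-based,338.4,6.9,72.4,4.3,1.9,0.3,0.5,0.9,4.9,1
gf21,Lasagne sheets,pasta/cereal-based,373.0,7.0,76.3,0.8,4.0,1.1,1.6,0.8,2.4,1
gf22,Vermicelli,pasta/cereal-based,371.2,12.5,71.6,2.0,3.4,0.4,1.0,1.7,13.5,1
gf23,Tagliatelli,pasta/cereal-based,370.9,12.1,72.0,1.9,3.3,0.4,1.0,1.7,13.1,1
gf24,Cous Cous,pasta/cereal-based,345.0,8.8,73.8,1.5,1.1,0.1,0.4,0.4,5.0,1
gf25,Granola (chocolate),cereals,392.3,5.5,72.6,34.0,8.5,4.7,3.1,0.6,4.6,1
gf26,Granola (nuts),cereals,478.0,7.1,64.9,16.7,21.0,7.7,10.3,2.5,4.8,1
gf27,Cornflakes,cereals,322.4,8.5,62.9,1.4,3.7,0.6,1.1,1.6,7.6,1
gf28,Shortbread,cookies/cakes,385.3,3.3,73.6,13.8,8.3,2.7,3.9,1.5,1.2,1
gf29,Neapolitan wafers (original),cookies/cakes,236.0,2.5,22.9,18.1,15.0,8.3,5.2,1.1,3.3,1
gf30,Cookie (chocolate),cookies/cakes,479.2,2.0,64.3,5.7,23.8,11.9,8.5,2.5,2.3,1
gf31,Mignon wafers (hazelnut),cookies/cakes,507.9,5.0,54.0,41.7,30.4,13.9,11.9,3.7,5.6,1
gf32,Marble cake,cookies/cakes,403.7,5.4,48.1,20.7,22.6,3.8,10.2,7.4,0.8,1
gf33,Ladyfinger,cookies/cakes,356.9,5.7,74.6,33.1,3.5,1.0,1.4,0.6,2.5,1
gf34,Cookie (whole-grain),cookies/cakes,471.1,4.6,71.8,21.1,18.2,7.8,6.8,2.8,3.6,1
gf35,Granola bar,cookies/cakes,400.8,7.2,59.2,25.0,14.8,7.0,5.3,1.7,12.9,1
gf36,Cookie (orange),cookies/cakes,433.0,6.2,60.2,49.7,18.3,10.5,5.5,1.4,2.6,2
gf37,Apple strudel,cookies/cakes,270.9,4.2,43.2,18.1,8.7,3.4,2.9,2.2,1.6,1
gf38,Muffin,cookies/cakes,371.6,5.2,55.8,30.0,14.6,4.1,3.4,2.2,3.5,1
gf39,Cracker,snacks,340.8,10.1,43.5,0.0,13.8,9.3,3.3,0.4,0.3,1
gf40,Brezels,snacks,449.7,0.5,65.5,0.8,20.6,9.8,7.5,2.4,0.8,1
gf41,Grissini,snacks,392.5,2.0,67.4,2.6,12.6,3.9,6.1,2.4,0.7,1
gf42,Saltsticks,snacks,480.9,0.6,72.0,1.5,21.1,10.3,7.8,2.2,0.8,1
gf43,Wafers (plain),snacks,329.7,8.6,63.8,1.4,4.1,0.6,1.2,1.8,7.7,1
gf44,Pizza (salami),convenience,235.1,8.0,24.8,2.8,11.5,4.8,4.1,1.9,1.5,1
gf45,Pizza (margherita),convenience,209.1,6.3,27.6,3.5,8.0,3.8,2.5,1.3,2.0,1
gf46,Lasagne,convenience,170.4,7.4,16.4,2.2,8.3,3.8,3.2,0.8,1.1,1
gf47,Chicken nuggets,convenience,251.2,15.3,22.5,0.5,11.0,1.5,4.2,4.8,3.0,1
gf48,Fish sticks,convenience,216.0,9.2,28.1,4.0,7.3,0.8,1.8,3.8,1.9,1
gf49,Tortellini (pork),convenience,285.3,7.7,48.1,1.3,6.6,2.5,2.5,1.0,1.7,1
gf50,Soup (potato and leek),convenience,355.9,16.2,47.7,7.9,10.4,2.2,4.3,2.6,8.3,1
gf51,Soup (mushrooms),convenience,431.4,15.5,43.4,13.7,21.7,2.1,10.2,5.7,1.6,1
gf52,Wafer-cone (icecream filling),convenience,278.0,5.2,27.8,24.2,16.2,5.9,7.0,2.9,3.5,1
gf53,Pudding (semolina),convenience,362.5,6.2,82.0,14.8,0.6,0.1,0.2,0.2,1.8,1
gf54,Baked pastry case,convenience,483.9,4.3,43.3,21.6,32.9,15.7,12.0,3.6,4.4,1
gf55,Wafer (Oblate),convenience,329.2,1.1,79.1,0.2,0.4,0.1,0.1,0.2,1.2,1
gf56,Rice drink (natural),convenience,56.9,1.1,11.0,0.2,0.9,0.1,0.4,0.3,0.4,1
gf57,Flaky pastry,convenience,389.5,1.4,31.6,2.05,29.0,8.1,7.3,12.3,5.3,1
gf58,"Frozen cake (almond, chocolate)",convenience,405.2,7.0,25.1,24.4,31.1,10.9,13.1,4.3,2.0,1
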