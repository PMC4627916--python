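product_id,name,category,sodium_mg,cholesterol_mg,iron_mg,calcium_mg,potassium_mg,zinc_mg,phosphorus_mg,vitC_mg,vitD_ug,vitE_mg,retinol_ug,bcarotene_ug,thiamin_mg,riboflavin_mg,niacin_mg,pooled_weight
gf01,Flour,flour/bake mix,3.02,0.00,1.42,32.16,147.84,0.99,78.76,0.00,0.00,0.11,0.00,0.02,0.08,0.03,0.29,2
gf02,Bake mix white (cake),flour/bake mix,39.67,0.00,1.17,54.73,240.21,1.08,204.11,0.12,0.00,0.04,0.00,0.00,0.03,0.02,0.29,1
gf03,Bake mix brown (cake),flour/bake mix,41.71,9.47,1.23,17.52,252.71,0.79,118.76,0.32,0.00,0.06,0.00,0.00,0.02,0.02,0.29,1
gf04,Bake mix (Pizza),flour/bake mix,783.75,0.00,1.49,89.31,347.84,1.64,720.85,0.39,0.00,0.08,0.00,0.00,0.06,0.05,1.14,2
gf05,Breadcrumbs,flour/bake mix,196.33,0.04,2.25,31.67,182.99,1.88,183.23,0.00,0.00,1.02,0.00,4.51,0.25,0.04,0.31,2
gf06,Rustic bread,bread/bakery,120.53,0.00,0.38,10.58,75.45,0.48,35.90,0.00,0.00,1.01,0.00,0.00,0.06,0.02,0.48,1
gf07,Whole-grain bread,bread/bakery,685.79,0.00,2.41,96.43,304.10,1.70,208.75,0.01,0.00,0.23,0.00,0.01,0.21,0.10,1.33,1
gf08,Toast,bread/bakery,394.29,0.02,1.58,34.01,273.02,1.24,135.35,0.03,0.00,2.05,0.00,0.37,0.17,0.11,1.92,2
gf09,Bun,bread/bakery,402.11,4.02,0.60,17.67,52.68,0.39,36.52,0.00,0.00,0.48,0.00,1.28,0.03,0.06,0.48,1
gf10,Ciabatta,bread/bakery,355.74,0.00,1.03,17.15,117.38,0.86,91.38,1.20,0.00,1.05,0.00,0.08,0.14,0.09,0.97,1
gf11,Raisin bread,bread/bakery,299.48,0.37,1.01,59.31,157.72,0.73,80.86,0.43,0.00,0.08,0.02,0.04,0.07,0.09,0.51,1
gf12,Scone,bread/bakery,314.90,32.64,0.82,30.76,91.38,0.50,73.71,0.01,0.00,0.19,0.06,0.05,0.07,0.14,1.09,1
gf13,Baguette,bread/bakery,336.38,0.00,0.66,13.96,120.93,0.41,48.25,0.84,0.00,1.41,0.00,0.01,0.07,0.06,0.62,1
gf14,Lye Pretzel,bread/bakery,790.76,7.06,0.40,124.30,137.68,0.57,78.43,13.10,0.00,0.49,0.02,1.29,0.04,0.15,0.15,1
gf15,Rusk,bread/bakery,5.52,0.01,1.06,21.34,11.95,0.40,20.24,0.00,0.00,0.08,0.00,1.00,0.00,0.01,0.09,1
gf16,Crispbread,bread/bakery,547.20,0.00,0.67,11.61,99.13,0.67,109.04,0.00,0.00,0.24,0.00,0.04,0.11,0.04,1.38,1
gf17,Wraps,bread/bakery,402.35,0.63,0.21,18.09,83.57,0.19,39.96,0.25,0.23,0.07,0.05,0.06,0.03,0.01,0.58,1
gf18,Fusilli,pasta/cereal-based,1.88,0.00,1.80,14.67,114.68,1.87,205.75,0.00,0.00,0.81,0.00,0.21,0.33,0.10,1.76,1
gf19,Spaghetti,pasta/cereal-based,1.00,0.00,2.40,18.00,120.00,2.50,256.00,0.00,0.00,1.11,0.00,0.30,0.44,0.13,1.93,1
gf20,Penne,pasta/cereal-based,1.90,0.00,3.15,22.73,198.37,1.43,211.40,0.00,0.00,0.48,0.00,0.12,0.28,0.12,1.61,1
gf21,Lasagne sheets,pasta/cereal-based,55.98,146.52,1.37,30.53,91.97,1.32,144.47,0.00,0.00,0.89,0.10,0.04,0.10,0.18,0.52,1
gf22,Vermicelli,pasta/cereal-based,6.71,0.00,3.81,45.15,297.12,3.05,327.38,0.93,0.00,1.68,0.00,0.31,0.51,0.16,2.14,1
gf23,Tagliatelli,pasta/cereal-based,5.94,0.00,3.65,41.70,274.68,3.02,321.78,0.80,0.00,1.62,0.00,0.32,0.51,0.16,2.14,1
gf24,Cous Cous,pasta/cereal-based,1.00,0.00,1.00,4.00,80.00,0.41,73.00,0.00,0.00,0.52,0.00,0.26,0.13,0.04,1.20,1
gf25,Granola (chocolate),cereals,504.01,15.77,1.51,17.98,265.98,0.52,73.86,0.13,0.00,0.25,0.00,0.51,0.05,0.06,0.96,1
gf26,Granola (nuts),cereals,393.96,0.16,1.72,44.88,314.76,1.60,174.62,0.11,0.00,3.54,0.00,1.78,0.20,0.09,1.40,1
gf27,Cornflakes,cereals,575.88,0.00,1.52,8.61,265.44,1.45,208.76,0.00,0.00,1.47,0.00,0.90,0.35,0.20,1.47,1
gf28,Shortbread,cookies/cakes,408.14,17.31,0.66,33.19,79.97,0.59,72.93,0.22,0.00,0.84,0.02,9.02,0.05,0.10,0.73,1
gf29,Neapolitan wafers (original),cookies/cakes,16.20,21.70,0.71,8.86,259.18,0.59,61.06,0.01,0.00,0.12,0.00,0.01,0.03,0.03,0.37,1
gf30,Cookie (chocolate),cookies/cakes,199.30,3.37,0.82,13.20,91.10,0.73,57.96,0.00,0.00,1.66,0.00,4.50,0.05,0.02,0.26,1
gf31,Mignon wafers (hazelnut),cookies/cakes,417.91,28.84,2.70,28.12,476.92,1.16,124.82,0.02,0.00,1.31,0.00,0.03,0.09,0.06,0.68,1
gf32,Marble cake,cookies/cakes,54.88,138.60,1.32,22.11,103.26,0.76,98.91,0.00,0.00,12.54,0.10,0.02,0.05,0.15,0.24,1
gf33,Ladyfinger,cookies/cakes,98.46,141.37,1.00,37.26,79.88,0.80,100.96,0.00,0.00,0.72,0.10,0.00,0.05,0.15,0.28,1
gf34,Cookie (whole-grain),cookies/cakes,295.19,5.16,1.17,15.24,68.83,0.78,89.30,0.13,0.00,0.37,0.00,0.12,0.14,0.05,0.87,1
gf35,Granola bar,cookies/cakes,237.91,4.24,2.14,96.16,292.51,1.37,170.55,0.45,0.00,1.00,0.01,0.16,0.19,0.19,1.23,1
gf36,Cookie (orange),cookies/cakes,190.66,23.28,1.74,103.46,389.10,0.83,120.50,4.78,0.00,0.39,0.06,0.27,0.08,0.13,0.45,2
gf37,Apple strudel,cookies/cakes,102.98,1.83,1.13,177.03,240.82,0.68,128.36,4.75,0.00,0.16,0.05,0.08,0.07,0.27,0.25,1
gf38,Muffin,cookies/cakes,247.84,79.20,2.66,29.50,219.98,0.74,102.31,0.00,0.00,3.54,0.06,0.01,0.06,0.11,0.30,1
gf39,Cracker,snacks,2416.36,47.71,1.40,434.99,83.08,2.05,305.78,0.43,0.00,0.41,0.13,0.06,0.03,0.12,0.48,1
gf40,Brezels,snacks,554.28,0.20,0.67,11.72,17.23,0.45,26.93,0.00,0.00,1.48,0.00,4.26,0.01,0.03,0.21,1
gf41,Grissini,snacks,226.87,20.01,0.63,52.59,64.73,0.62,62.82,0.06,0.00,1.31,0.03,15.02,0.02,0.09,0.07,1
gf42,Saltsticks,snacks,1007.36,0.21,0.93,15.82,25.22,0.47,30.69,0.00,0.00,1.56,0.00,4.47,0.02,0.04,0.34,1
gf43,Wafers (plain),snacks,119.98,0.01,1.50,8.15,268.55,1.47,211.73,0.02,0.00,1.61,0.00,0.92,0.36,0.20,1.49,1
gf44,Pizza (salami),convenience,614.15,22.66,0.97,103.75,275.57,1.13,115.28,7.43,0.00,3.23,0.04,0.24,0.11,0.11,1.68,1
gf45,Pizza (margherita),convenience,437.51,14.95,0.68,110.73,266.87,0.85,106.10,6.97,0.00,2.97,0.05,0.26,0.05,0.10,1.02,1
gf46,Lasagne,convenience,450.21,38.88,0.79,56.08,211.47,1.38,99.60,5.51,0.02,1.14,0.04,0.24,0.11,0.13,1.51,1
gf47,Chicken nuggets,convenience,396.19,35.00,1.34,16.80,158.47,1.37,179.53,0.05,0.00,5.46,0.00,0.16,0.14,0.09,4.71,1
gf48,Fish sticks,convenience,378.34,23.54,1.19,24.87,128.33,0.49,142.50,0.24,0.00,4.04,0.00,0.11,0.12,0.22,1.62,1
gf49,Tortellini (pork),convenience,628.05,72.33,1.49,51.06,118.68,1.64,122.19,1.06,0.01,0.75,0.04,0.04,0.24,0.12,1.38,1
gf50,Soup (potato and leek),convenience,3801.76,1.03,2.53,80.57,1014.25,0.88,260.47,11.70,0.00,1.61,0.00,0.42,0.17,0.28,4.63,1
gf51,Soup (mushrooms),convenience,472.57,0.43,0.89,17.52,104.01,0.22,34.90,0.95,0.00,3.82,0.00,0.68,0.04,0.07,0.91,1
gf52,Wafer-cone (icecream filling),convenience,101.42,22.61,1.39,97.43,358.09,0.78,127.37,0.81,0.12,3.66,0.02,0.04,0.04,0.16,0.37,1
gf53,Pudding (semolina),convenience,117.48,0.00,0.54,9.64,91.27,0.50,79.69,0.10,0.00,0.09,0.00,0.00,0.06,0.02,1.18,1
gf54,Baked pastry case,convenience,108.30,0.32,1.61,30.08,138.24,1.30,202.23,0.70,0.00,2.87,0.00,6.82,0.18,0.09,1.91,1
gf55,Wafer (Oblate),convenience,6.98,0.00,1.80,31.88,26.15,0.43,35.54,0.00,0.00,0.12,0.00,0.03,0.05,0.02,0.33,1
gf56,Rice drink (natural),convenience,52.58,0.00,0.23,12.47,17.01,0.20,15.55,0.00,0.00,0.51,0.00,0.00,0.01,0.00,0.19,1
gf57,Flaky pastry,convenience,412.00,2.35,0.22,49.65,47.07,0.20,24.56,0.13,0.03,2.10,0.00,0.17,0.24,0.01,0.22,1
gf58,"Frozen cake (almond, chocolate)",convenience,120.14,170.20,1.69,39.44,219.39,0.90,126.96,0.21,0.13,4.26,0.15,2.19,0.06,0.16,0.38,1
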