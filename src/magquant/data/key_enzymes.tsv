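enzyme_label	ko_ids	aggregation_mode	ad_category
cellulase (EC 3.2.1.4)	K01179	sum_similar	hydrolysis
beta-glucosidase (EC 3.2.1.21)	K05349,K05350	sum_similar	hydrolysis
alpha-amylase (EC 3.2.1.1)	K01176	sum_similar	hydrolysis
endo-1,4-beta-xylanase (EC 3.2.1.8)	K01181	sum_similar	hydrolysis
acetate kinase (EC 2.7.2.1)	K00925	sum_similar	acidogenesis
phosphate acetyltransferase (EC 2.3.1.8)	K00625,K13788	sum_similar	acidogenesis
butyrate kinase (EC 2.7.2.7)	K00929	sum_similar	acidogenesis
L-lactate dehydrogenase (EC 1.1.1.27)	K00016	sum_similar	acidogenesis
pyruvate:ferredoxin oxidoreductase (EC 1.2.7.1)	K00169,K00170,K00171,K00172	median_subunits	acidogenesis
formate dehydrogenase (EC 1.17.1.9)	K00122,K00123	median_subunits	acetogenesis
acetyl-CoA synthase/CO dehydrogenase (EC 2.3.1.169)	K00192,K00193,K00194,K00197	median_subunits	acetogenesis
electron transfer flavoprotein EtfAB	K03521,K03522	median_subunits	acetogenesis
formylmethanofuran dehydrogenase (EC 1.2.7.12)	K00200,K00201,K00202,K00203,K00205	median_subunits	hydrogenotrophic_methanogenesis
methenyltetrahydromethanopterin cyclohydrolase (EC 3.5.4.27)	K01499	sum_similar	hydrogenotrophic_methanogenesis
methylenetetrahydromethanopterin dehydrogenase (EC 1.5.98.1)	K00319	sum_similar	hydrogenotrophic_methanogenesis
methylenetetrahydromethanopterin reductase (EC 1.5.98.2)	K00320	sum_similar	hydrogenotrophic_methanogenesis
tetrahydromethanopterin S-methyltransferase (EC 2.1.1.86)	K00577,K00578,K00579,K00580,K00581	median_subunits	hydrogenotrophic_methanogenesis
methyl-coenzyme M reductase (EC 2.8.4.1)	K00399,K00401,K00402	median_subunits	hydrogenotrophic_methanogenesis
heterodisulfide reductase HdrABC	K03388,K03389,K03390	median_subunits	hydrogenotrophic_methanogenesis
acetyl-CoA synthetase AMP-forming (EC 6.2.1.1)	K01895	sum_similar	acetoclastic_methanogenesis
acetyl-CoA decarbonylase/synthase complex	K00193,K00194,K00197	median_subunits	acetoclastic_methanogenesis
methanol:coenzyme M methyltransferase (EC 2.1.1.90)	K14080,K04480,K14081	median_subunits	methylotrophic_methanogenesis
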