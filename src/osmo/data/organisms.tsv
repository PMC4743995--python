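organism_id	display_name	taxonomy_group	habitat	cell_wall	ic10	ic25	ic50	n_bio_replicates
atum	Agrobacterium tumefaciens	alpha-proteobacteria	plant-associated	thin	NA	NA	NA	4
bsub	Bacillus subtilis	firmicutes	free-living	thick	NA	NA	NA	4
cglu	Corynebacterium glutamicum	actinobacteria	free-living	thick	NA	NA	NA	4
ecol	Escherichia coli	gamma-proteobacteria	animal-associated	thin	NA	NA	NA	4
lcas	Lactobacillus casei	firmicutes	animal-associated	thick	NA	NA	NA	4
msme	Mycobacterium smegmatis	actinobacteria	free-living	thick	NA	NA	NA	4
pver	Paracoccus versutus	alpha-proteobacteria	free-living	thin	NA	NA	NA	4
pflu	Pseudomonas fluorescens	gamma-proteobacteria	plant-associated	thin	NA	NA	NA	4
pput	Pseudomonas putida	gamma-proteobacteria	free-living	thin	NA	NA	NA	4
rsph	Rhodobacter sphaeroides	alpha-proteobacteria	free-living	thin	NA	NA	NA	4
scer	Saccharomyces cerevisiae	fungi	plant-associated	thick	NA	NA	NA	4
spom	Schizosaccharomyces pombe	fungi	free-living	thick	NA	NA	NA	4
smel	Sinorhizobium meliloti	alpha-proteobacteria	plant-associated	thin	NA	NA	NA	4
zmob	Zymomonas mobilis	alpha-proteobacteria	plant-associated	thin	NA	NA	1500	4
hdf	Homo sapiens HDF	human	animal-associated	none	NA	NA	NA	3
mcf7	Homo sapiens MCF7	human	animal-associated	none	NA	NA	150	3
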