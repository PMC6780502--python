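antibody_id	name	immunogen_source	origin	cluster	phylum	has_tracer	reference
Bou.I	Bou. I	Boulby Mine I (wet and pink salt)	mase_environmental	environmental extracts		1	-
Bou.II	Bou. II	Boulby Mine II	mase_environmental	environmental extracts		1	-
MSIs	MSIs	Mülbach Islinger-Regensburg (cold spring-sediment)	mase_environmental	environmental extracts		1	-
SMs	SMs	Sippenauer Moore-Regensburg (cold spring-sediment)	mase_environmental	environmental extracts		1	-
IS.SS1	IS. SS1	Grænavatn Lake-Iceland (sediment)	mase_environmental	environmental extracts		1	-
MASE-BB-1	MASE-BB-1	Halanaerobium sp. (isolate from Boulby)	mase_isolate	anaerobic isolates	Firmicutes	1	B30
MASE-IM-5	MASE-IM-5	Trichococcus sp. 37AN3 (Mülbach Islinger)	mase_isolate	anaerobic isolates	Firmicutes	1	B30
MASE-IM-4	MASE-IM-4	Clostridium sp. DSM632 (Mülbach Islinger)	mase_isolate	anaerobic isolates	Firmicutes	1	B30
MASE-SM-3	MASE-SM-3	Hafnia sp. (Sippenauer Moore)	mase_isolate	anaerobic isolates	Proteobacteria	1	B30
MASE-SM-2	MASE-SM-2	Clostridium sp. (Sippenauer Moore)	mase_isolate	anaerobic isolates	Firmicutes	1	B30
MASE-SM-1	MASE-SM-1	Methanomethylovorans sp. (Sippenauer Moore)	mase_isolate	anaerobic isolates	Euryarchaeota	1	B30
MASE-IM-7	MASE-IM-7	Desulfovibrio sp. (Mülbach Islinger)	mase_isolate	anaerobic isolates	Proteobacteria	1	B30
MASE-LG-2	MASE-LG-2	Pelosinus sp. (Grænavatn Lake)	mase_isolate	anaerobic isolates	Firmicutes	1	B30
ET2	ET2	Bacteroides xylanoliticus X5-1 (Grænavatn Lake)	mase_isolate	anaerobic isolates	Bacteroidetes	1	up
MASE-Glacier-SS3	MASE-Glacier-SS3	Rhanella sp. (Kaunertal Glacier)	mase_isolate	anaerobic isolates	Proteobacteria	1	B30
IVE7C1	IVE7C1	Halothiobacillus neapolitanus	prior_collection	prior collection cultures	Proteobacteria	1	B40
IVG5C1	IVG5C1	Sulfobacillus acidophilus	prior_collection	prior collection cultures	Firmicutes	1	B40
IVI12C1	IVI12C1	Geobacter metallireducens	prior_collection	prior collection cultures	Proteobacteria	1	B62
IVI20C1	IVI20C1	Salinibacter ruber M8	prior_collection	halophilic cultures	Bacteroidetes	1	B40
IVI21C1	IVI21C1	Salinibacter ruber PR1	prior_collection	halophilic cultures	Bacteroidetes	1	B40
IVI24C1	IVI24C1	Thessaracoccus lapidicapta	prior_collection	prior collection cultures	Actinobacteria	1	B66
IVJ1C1	IVJ1C1	Haloferax mediterranei	prior_collection	halophilic cultures	Euryarchaeota	1	B62
IVJ8C1	IVJ8C1	Halorubrum sp.	prior_collection	halophilic cultures	Euryarchaeota	1	B40
IVJ9C1	IVJ9C1	Halobacterium sp.	prior_collection	halophilic cultures	Euryarchaeota	1	B40
IVK19C1	IVK19C1	Chroococcidiopsis O29	prior_collection	prior collection cultures	Cyanobacteria	1	up
VD2BF	VD2BF	Biofilm from Mansimongs Mines Southafrica	prior_collection	prior collection cultures		1	up
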