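ko_id	optimum	description	sign	tcdb
K01546	Both	K+-transporting ATPase ATPase A chain	-	Yes
K01547	Both	K+-transporting ATPase ATPase B chain	-	Yes
K01548	Both	K+-transporting ATPase ATPase C chain	-	Yes
K03310	Both	Alanine or glycine:cation symporter, AGCS family	+	Yes
K03499	Both	Trk system potassium uptake protein	+	Yes
K07301	Both	Cation:H+ antiporter	+	Yes
K08974	Both	Putative membrane protein	+	No
K03543	pH	Membrane fusion protein, multidrug efflux system	-	Yes
K03446	pH	MFS transporter, DHA2 family, multidrug resistance protein	-	Yes
K08677	pH	Kumamolisin	-	No
K07799	pH	Membrane fusion protein, multidrug efflux system	-	Yes
K06045	pH	Squalene-hopene/tetraprenyl-beta-curcumene cyclase	-	Yes
K15495	pH	Molybdate/tungstate transport system substrate-binding protein	-	Yes
K15496	pH	Molybdate/tungstate transport system permease protein	-	Yes
K14393	pH	Cation/acetate symporter	+	Yes
K02168	pH	Choline/glycine/proline betaine transport protein	+	Yes
K07393	pH	Putative glutathione S-transferase	+	No
K06718	pH	L-2,4-diaminobutyric acid acetyltransferase	+	No
K06720	pH	L-ectoine synthase	+	No
K09908	pH	Uncharacterized protein	+	No
K06213	pH	Magnesium transporter	+	Yes
K05565	pH	Multicomponent Na+:H+ antiporter subunit A	+	Yes
K05567	pH	Multicomponent Na+:H+ antiporter subunit C	+	Yes
K05568	pH	Multicomponent Na+:H+ antiporter subunit D	+	Yes
K05569	pH	Multicomponent Na+:H+ antiporter subunit E	+	Yes
K05570	pH	Multicomponent Na+:H+ antiporter subunit F	+	Yes
K05571	pH	Multicomponent Na+:H+ antiporter subunit G	+	Yes
K14683	pH	Solute carrier family 34 (sodium-dependent phosphate cotransporter)	+	Yes
K14445	pH	Solute carrier family 13 (sodium-dependent dicarboxylate transporter), member 2/3/5	+	Yes
K03451	pH	Betaine/carnitine transporter, BCCT family	+	Yes
K03308	pH	Neurotransmitter:Na+ symporter, NSS family	+	Yes
K08714	pH	Voltage-gated sodium channel	+	Yes
K03826	pH	Putative acetyltransferase	+	No
K03975	Salinity	Membrane-associated protein	-	Yes
K08223	Salinity	MFS transporter, fosmidomycin resistance protein	-	Yes
K07646	Salinity	Two-component system, OmpR family, sensor histidine kinase KdpD	-	No
K03549	Salinity	KUP system potassium uptake protein	-	Yes
K03699	Salinity	Putative hemolysin	-	No
K02276	Salinity	Cytochrome c oxidase subunit III	+	No
K07160	Salinity	UPF0271 protein	+	No
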