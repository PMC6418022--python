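species	v1	v2	v3
Ambystoma tigrinum tigrinum	-4.31380	-1.10950	-2.39820
Bufo gargarizans	-4.23240	-1.35480	-2.26260
Rana plancyi	-4.09750	-1.29530	-2.25390
Ara ararauna	-4.23570	-1.83360	-2.19300
Archilochus colubris	-4.27030	-1.84760	-2.21910
Columba livia	-4.21960	-1.84640	-2.20990
Gallus gallus	-4.17150	-1.91490	-2.17750
Ninox strenua	-4.21900	-2.02220	-2.21770
Carcharodon carcharias	-4.18720	-1.46250	-2.31750
Cyprinus carpio	-4.47010	-1.58480	-2.28400
Dicentrarchus labrax	-4.35900	-1.18640	-2.12810
Poecilia reticulata	-4.20920	-1.42200	-2.30390
Didelphis virginiana	-4.29970	-1.33300	-2.40300
Macropus giganteus	-4.28390	-1.68110	-2.34200
Vombatus ursinus	-4.31840	-1.74230	-2.33970
Bos taurus	-4.37060	-1.56840	-2.34500
Canis lupus familiaris	-4.28210	-1.42680	-2.35010
Capra aegagrus	-4.35320	-1.60750	-2.34750
Felis catus	-4.39050	-1.53750	-2.34000
Mus musculus musculus	-4.33330	-1.55190	-2.37410
Oryctolagus cuniculus	-4.24440	-1.48650	-2.33690
Rattus rattus	-4.33380	-1.58590	-2.35240
Gorilla gorilla gorilla	-4.16280	-1.80220	-2.27510
Homo sapiens	-4.16480	-1.85860	-2.26910
Lemur catta	-4.24340	-1.54580	-2.36720
Pan paniscus	-4.15450	-1.82670	-2.28690
Pan troglodytes	-4.15590	-1.82770	-2.28130
Alligator mississippiensis	-4.26190	-1.71650	-2.26170
Chelydra serpentina	-4.37120	-1.61300	-2.35910
Crocodylus niloticus	-4.44740	-1.61700	-2.27800
Crotalus horridus	-4.31660	-1.78940	-2.27140
Naja naja	-4.35360	-1.72560	-2.28610
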