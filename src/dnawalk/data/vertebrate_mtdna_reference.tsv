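species	xi	H	alpha_RY	alpha_SW	alpha_KM	beta_RY	beta_SW	beta_KM
Ambystoma tigrinum tigrinum	1.081	1.9059	0.91798	0.91328	0.90701	0.67836	0.90728	0.71664
Bufo gargarizans	1.2617	1.9598	0.91688	0.91187	0.91191	0.75691	0.76766	0.76934
Rana plancyi	1.3562	1.9591	0.91695	0.91259	0.91228	0.78803	0.74711	0.74653
Ara ararauna	1.2537	1.9421	0.91657	0.91337	0.9133	0.74963	0.65734	0.86363
Archilochus colubris	1.2296	1.9409	0.91621	0.91298	0.91332	0.74416	0.6971	0.86625
Columba livia	1.2664	1.9381	0.91696	0.91336	0.91383	0.76494	0.67966	0.86371
Gallus gallus	1.2851	1.9316	0.91564	0.91109	0.91368	0.7581	0.66958	0.87402
Ninox strenua	1.2421	1.926	0.91569	0.91662	0.91341	0.75282	0.6407	0.88804
Carcharodon carcharias	1.249	1.9444	0.91506	0.91385	0.91056	0.74703	0.80776	0.79693
Cyprinus carpio	1.0981	1.9577	0.91759	0.91463	0.91045	0.67192	0.75648	0.8331
Dicentrarchus labrax	1.2372	1.9765	0.91881	0.90116	0.91412	0.75312	0.73671	0.72254
Poecilia reticulata	1.2228	1.9529	0.91631	0.91447	0.90864	0.73809	0.78308	0.78935
Didelphis virginiana	1.1117	1.8969	0.91844	0.91408	0.90997	0.70386	0.90263	0.7744
Macropus giganteus	1.1762	1.9275	0.91811	0.91388	0.91113	0.73178	0.8363	0.84188
Vombatus ursinus	1.164	1.9254	0.9179	0.91391	0.91207	0.72691	0.83327	0.85255
Bos taurus	1.1332	1.9339	0.91704	0.9137	0.91125	0.69678	0.84215	0.82662
Canis lupus familiaris	1.1848	1.9441	0.91666	0.91426	0.91009	0.71743	0.84081	0.79415
Capra aegagrus	1.1441	1.9292	0.91783	0.9136	0.91174	0.69553	0.84634	0.83395
Felis catus	1.1398	1.9429	0.91755	0.91438	0.91172	0.70012	0.82755	0.82021
Mus musculus musculus	1.1316	1.9154	0.91641	0.91368	0.91138	0.68457	0.87555	0.82526
Oryctolagus cuniculus	1.2169	1.9403	0.91665	0.91411	0.91117	0.7394	0.82727	0.80349
Rattus rattus	1.1465	1.9219	0.91655	0.91301	0.9119	0.70334	0.85943	0.82893
Gorilla gorilla gorilla	1.2706	1.9322	0.91509	0.91436	0.91224	0.76455	0.7491	0.85718
Homo sapiens	1.2716	1.9305	0.91549	0.91484	0.91255	0.76264	0.73476	0.8657
Lemur catta	1.1869	1.9246	0.91821	0.91424	0.91033	0.72169	0.86066	0.81856
Pan paniscus	1.2711	1.9272	0.91545	0.91465	0.91235	0.76222	0.75973	0.86114
Pan troglodytes	1.2717	1.9293	0.91548	0.9146	0.91225	0.76283	0.75342	0.86122
Alligator mississippiensis	1.2338	1.9383	0.91704	0.91213	0.91343	0.74351	0.76308	0.84625
Chelydra serpentina	1.1259	1.9205	0.91732	0.9142	0.91211	0.68238	0.85194	0.83671
Crocodylus niloticus	1.1347	1.9504	0.91653	0.91448	0.91326	0.69992	0.75112	0.83504
Crotalus horridus	1.1898	1.9337	0.91366	0.91336	0.91345	0.70735	0.75833	0.86203
Naja naja	1.1597	1.9324	0.91379	0.91192	0.913	0.69597	0.79567	0.85368
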