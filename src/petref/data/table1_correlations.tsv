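region	strongest_conventional	median_conventional	strongest_digital	median_digital
Precentral_R	-0.573688445	0.279184148	-0.581382052	0.293280215
Precentral_L	-0.622302284	0.232181965	-0.628568612	0.266985128
Frontal_Sup_R	-0.600980191	0.319870899	-0.690629185	0.242280289
Frontal_Sup_L	-0.547693637	0.405334595	-0.599914817	0.443110434
Frontal_Sup_Orb_R	-0.629579861	0.084998269	-0.700581666	-0.108439103
Frontal_Sup_Orb_L	-0.547437357	0.192820744	-0.703649178	-0.033764917
Frontal_Mid_R	-0.553053145	0.349833531	-0.584128133	0.463018236
Frontal_Mid_L	-0.551382331	0.315606715	-0.610512904	0.39907714
Frontal_Mid_Orb_R	-0.55913071	0.098969813	-0.684911592	-0.036623595
Frontal_Mid_Orb_L	-0.445475539	0.255947537	-0.680085738	0.1323272
Frontal_Inf_Oper_R	-0.403554772	0.451057221	-0.584413796	0.431311318
Frontal_Inf_Oper_L	-0.346777766	0.545425764	-0.542003107	0.481079751
Frontal_Inf_Tri_R	-0.549174379	0.296954014	-0.608717652	0.267245207
Frontal_Inf_Tri_L	-0.558387379	0.286348933	-0.653848914	0.273189928
Frontal_Inf_Orb_R	-0.52705298	0.333803877	-0.6524112	0.21577136
Frontal_Inf_Orb_L	-0.464517096	0.368956454	-0.628902165	0.32330541
Rolandic_Oper_R	-0.566697841	0.243996131	-0.678571105	0.095847239
Rolandic_Oper_L	-0.618467447	0.211708259	-0.723144101	-0.112062758
Supp_Motor_Area_R	-0.517843026	0.180772399	-0.460519688	0.426544183
Supp_Motor_Area_L	-0.696169862	-0.02036436	-0.73268581	0.039897831
Olfactory_R	-0.388765983	0.487926686	-0.657210451	0.105375048
Olfactory_L	-0.528013879	0.384147962	-0.721491098	-0.122749257
Frontal_Sup_Medial_R	-0.358836732	0.524163102	-0.488283894	0.489288049
Frontal_Sup_Medial_L	-0.573032908	0.423672249	-0.735839552	0.25158455
Frontal_Med_Orb_R	-0.484358087	0.39321911	-0.615616599	0.337668074
Frontal_Med_Orb_L	-0.50075176	0.376511335	-0.74510263	0.041807974
Rectus_R	-0.55071263	0.351304466	-0.635567564	0.035246613
Rectus_L	-0.604668295	0.259112277	-0.671649932	-0.154421386
Insula_R	-0.626506716	0.161993577	-0.734040284	-0.072023968
Insula_L	-0.443959797	0.496975678	-0.56772327	0.513856619
Cingulum_Ant_R	-0.275972126	0.634247449	-0.400842278	0.640119849
Cingulum_Ant_L	-0.692031912	0.350939125	-0.78453279	0.189981663
Cingulum_Mid_R	-0.615009986	0.262411063	-0.579931165	0.467563092
Cingulum_Mid_L	-0.664484269	0.167834424	-0.730987309	0.232708068
Cingulum_Post_R	-0.526277264	0.019893397	-0.624772162	0.120155957
Cingulum_Post_L	-0.555623248	0.026567322	-0.634707019	0.240298045
Hippocampus_R	-0.74488582	-0.158224441	-0.776691477	-0.178442999
Hippocampus_L	-0.792432684	-0.401600367	-0.794914907	-0.355792507
ParaHippocampal_R	-0.547796599	0.135694163	-0.741894049	-0.03170524
ParaHippocampal_L	-0.691581684	-0.020746522	-0.774862984	-0.184001347
Amygdala_R	-0.690685381	-0.050409819	-0.738301387	-0.264093722
Amygdala_L	-0.675326502	-0.09187106	-0.738046871	-0.344906004
Calcarine_R	-0.597218653	0.004930533	-0.59736577	0.209424087
Calcarine_L	-0.641938573	-0.076213494	-0.693935653	-0.086552086
Cuneus_R	-0.726146822	-0.154685879	-0.621177518	0.096712726
Cuneus_L	-0.785087897	-0.348003457	-0.666285592	-0.124622161
Lingual_R	-0.634614302	-0.097770865	-0.643697071	-0.046781064
Lingual_L	-0.685486599	-0.166388559	-0.670109744	-0.04623892
Occipital_Sup_R	-0.701641346	-0.194678777	-0.646231705	-0.064989794
Occipital_Sup_L	-0.741727211	-0.306092732	-0.597199679	0.127544711
Occipital_Mid_R	-0.727813649	-0.364255804	-0.647178347	-0.059276144
Occipital_Mid_L	-0.718730655	-0.244437115	-0.672193986	0.035856165
Occipital_Inf_R	-0.723331225	-0.386129463	-0.668353467	-0.211046407
Occipital_Inf_L	-0.745424761	-0.389693675	-0.689600876	-0.207004321
Fusiform_R	-0.726536142	-0.195906801	-0.760147469	-0.312002428
Fusiform_L	-0.737547599	-0.265574857	-0.756777592	-0.30482379
Postcentral_R	-0.709883189	0.024251053	-0.626583194	0.099793863
Postcentral_L	-0.76459292	-0.110140116	-0.734129726	-0.048775906
Parietal_Sup_R	-0.710966862	-0.163768876	-0.600734839	0.175798905
Parietal_Sup_L	-0.639227666	-4.90902e-05	-0.542532856	0.337939446
Parietal_Inf_R	-0.620798761	0.113031765	-0.541267618	0.442951513
Parietal_Inf_L	-0.554435839	0.25511845	-0.519628	0.459809369
SupraMarginal_R	-0.642901203	0.143077102	-0.631066657	0.16035289
SupraMarginal_L	-0.67010586	0.198101079	-0.629274111	0.305772909
Angular_R	-0.637290184	-0.021187495	-0.576971854	0.223955824
Angular_L	-0.611346979	0.099585441	-0.577059191	0.293618718
Precuneus_R	-0.745445943	-0.14394911	-0.687422118	0.094901913
Precuneus_L	-0.757202509	-0.219708792	-0.708572999	0.033021343
Paracentral_Robule_R	-0.778348539	-0.344721681	-0.702759859	-0.103953847
Paracentral_Robule_L	-0.784491443	-0.417984838	-0.794021505	-0.424682684
Caudate_R	0.307397852	0.497272916	0.398152235	0.640465612
Caudate_L	-0.524293718	0.387711671	-0.711582026	0.385198422
Putamen_R	-0.602942275	0.125257327	-0.701652279	-0.198897079
Putamen_L	-0.630316648	-0.007083048	-0.70161431	-0.11815898
Pallidum_R	-0.510633293	0.20883992	-0.770671936	-0.407366194
Pallidum_L	-0.448907585	0.271878766	-0.709597016	-0.223370032
Thalamus_R	-0.507908201	0.263313022	-0.67710738	0.302515492
Thalamus_L	-0.654566592	-0.060126393	-0.74406809	-0.109863951
Heschl_R	-0.485771916	0.298329103	-0.55866801	0.43147372
Heschl_L	-0.472564385	0.35518222	-0.503638686	0.575685721
Temporal_Sup_R	-0.625069091	0.254407932	-0.624234384	0.348479101
Temporal_Sup_L	-0.68587206	0.168621993	-0.652154125	0.302844751
Temporal_Pole_Sup_R	-0.331232941	0.425860523	-0.44600523	0.406669675
Temporal_Pole_Sup_L	-0.363542986	0.354619085	-0.500438422	0.380854532
Temporal_Mid_R	-0.690671811	0.044779431	-0.658061148	0.11769236
Temporal_Mid_L	-0.697074384	0.064873746	-0.638795334	0.231016521
Temporal_Pole_Mid_R	-0.451855567	0.225791623	-0.644696334	0.035810993
Temporal_Pole_Mid_L	-0.457567288	0.245337503	-0.704001434	0.029743346
Temporal_Inf_R	-0.68436998	-0.104670403	-0.696015575	-0.063048755
Temporal_Inf_L	-0.669764664	-0.031455074	-0.689992535	0.035977061
Cerebelum_Crus1_R	-0.600476473	-0.004144622	-0.64067283	-0.112577583
Cerebelum_Crus1_L	-0.666707111	-0.13413203	-0.68045527	-0.193184819
Cerebelum_Crus2_R	-0.681004608	-0.302210346	-0.679835366	-0.196911931
Cerebelum_Crus2_L	-0.687555117	-0.232091696	-0.684717528	-0.150689558
Cerebelum_3_R	-0.631993976	-0.168105517	-0.69448275	-0.107741771
Cerebelum_3_L	-0.576269744	-0.009951379	-0.647040809	-0.007816927
Cerebelum_4_5_R	-0.650573984	-0.181355372	-0.687937783	-0.21895484
Cerebelum_4_5_L	-0.663071101	-0.077466212	-0.730497017	-0.123468168
Cerebelum_6_R	-0.677921489	-0.155131146	-0.710308279	-0.303651351
Cerebelum_6_L	-0.735262898	-0.279267569	-0.716515286	-0.28440532
Cerebelum_7b_R	-0.704269564	-0.332758809	-0.738855392	-0.400111216
Cerebelum_7b_L	-0.743454724	-0.403805093	-0.729542146	-0.333328681
Cerebelum_8_R	-0.729481495	-0.437717362	-0.812531147	-0.61846924
Cerebelum_8_L	-0.753248363	-0.500101319	-0.823696914	-0.630973003
Cerebelum_9_R	-0.695106139	-0.36420094	-0.79927817	-0.503436315
Cerebelum_9_L	-0.744673144	-0.476228365	-0.811756228	-0.579151524
Cerebelum_10_R	-0.548985851	-0.118360681	-0.717244723	-0.333550516
Cerebelum_10_L	-0.571047001	-0.201373641	-0.541209852	0.039102255
Vermis_1_2	-0.644498893	-0.180633313	-0.732799769	-0.208601441
Vermis_3	-0.584677906	-0.134242733	-0.671825282	-0.096599336
Vermis_4_5	-0.577923911	-0.137586851	-0.642737286	-0.089295963
Vermis_6	-0.531525033	-0.04047739	-0.610495443	-0.101942777
Vermis_7	-0.578924525	-0.093968004	-0.662218149	-0.224039981
Vermis_8	-0.756376798	-0.506853104	-0.790218976	-0.616443676
Vermis_9	-0.742895596	-0.469781549	-0.753866317	-0.457157983
Vermis_10	-0.667363951	-0.342948819	-0.714105274	-0.232058498
Midbrain	-0.71649863	-0.13811898	-0.748687248	-0.13147618
Pons	-0.718410905	-0.385970718	-0.818592258	-0.547892778
Medulla	-0.737949443	-0.406080404	-0.776357698	-0.371013333
Whole grey-matter	-0.738042818	0.124152213	-0.734258642	0.16754782686138
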