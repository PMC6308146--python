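id,primary_site,stage,rt_dose,concurrent_agent,time_to_failure_months,site,pattern
1,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,19,local,in_field
2,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Paclitaxel liposome,65,regional,in_field
3,Nasopharynx,III,44 Gy/20 + 22 Gy/10 + 4 Gy/2,Nedaplatin,14,local,in_field
4,Nasopharynx,III,44 Gy/20 + 22 Gy/10 + 4 Gy/2,Paclitaxel liposome,49,regional,marginal
5,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,30,local_regional,in_field
6,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,17,local_regional,in_field
7,Nasopharynx,III,44 Gy/20 + 22 Gy/10 + 4.4 Gy/2,Nedaplatin,54,regional,out_of_field
8,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,8,local,in_field
9,Nasopharynx,III,44 Gy/20 + 22 Gy/10 + 4.4 Gy/2,Docetaxel,34,local_regional,in_field
10,Nasopharynx,IVa,44 Gy/20 + 22 Gy/10 + 6.6 Gy/3,Nedaplatin,26,local,in_field
11,Nasopharynx,III,66 Gy/30 + 4 Gy/2,Docetaxel+oxaliplatin,27,local,in_field
12,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,11,regional,in_field
13,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Docetaxel,41,regional,in_field
14,Nasopharynx,IVa,50 Gy/25 + 20 Gy/10 + 4 Gy/2,Cetuximab+Nedaplatin,26,local,in_field
15,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Nedaplatin,26,regional,in_field
16,Nasopharynx,IVa,44 Gy/20 + 22 Gy/10 + 4.4 Gy/2,Docetaxel,51,regional,in_field
17,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Oxaliplatin,41,regional,in_field
18,Nasopharynx,III,44 Gy/20 + 22 Gy/10 + 4.4 Gy/2,Nedaplatin,33,local,in_field
19,Nasopharynx,III,50 Gy/25 + 20 Gy/10,Paclitaxel liposome,14,local,in_field
20,Nasopharynx,III,50 Gy/25 + 20 Gy/10 + 4 Gy/2,Nedaplatin,23,local,in_field
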