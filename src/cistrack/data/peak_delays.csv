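no,early_label,late_label,early,late,mean_s,sd_s,n,n_cells
1,EGFP-Emp46,Mnn9-mCherry,Emp46,Mnn9,31.0,24.1,10,6
2,GFP-Ypt1,Mnn9-mCherry,Ypt1,Mnn9,29.5,14.6,10,8
3,EGFP-Rer1,Mnn9-mCherry,Rer1,Mnn9,13.2,11.7,14,9
4,Erd2-GFP,Mnn9-mCherry,Erd2,Mnn9,16.4,10.3,18,14
5,EGFP-Emp46,iRFP-Rer1,Emp46,Rer1,3.9,9.0,31,15
6,Grh1-2xEGFP,Mnn9-mCherry,Grh1,Mnn9,37.1,16.8,14,12
7,Grh1-2xmCherry,EGFP-Rer1,Grh1,Rer1,26.2,17.7,13,9
8,Grh1-2xmCherry,GFP-Ypt1,Grh1,Ypt1,18.6,19.4,18,15
9,EGFP-Sed5,Mnn9-mCherry,Sed5,Mnn9,1.2,11.8,13,10
10,Mnn9-mCherry,GFP-Vrg4,Mnn9,Vrg4,11.9,11.6,18,13
11,Mnn9-mCherry,Sec21-2xEGFP,Mnn9,Sec21,37.9,33.2,17,13
12,Mnn9-mCherry,Mnn2-GFP,Mnn9,Mnn2,18.3,13.3,6,3
13,Sys1-iRFP,GFP-Ypt1,Sys1,Ypt1.2,19.7,16.3,18,13
14,GFP-Ypt1,Sec7-iRFP,Ypt1.2,Sec7,26.4,28.5,7,5
15,Gea1-EGFP,Mnn9-mCherry,Gea1,Mnn9,6.0,10.0,15,9
16,Mnn9-mCherry,Gea2-GFP,Mnn9,Gea2,76.2,21.7,13,11
17,Gnt1-GFP,Gea2-2xmCherry,Gnt1,Gea2,30.0,12.4,15,12
18,Gea2-2xmCherry,Tlg2-GFP,Gea2,Tlg2,9.3,11.0,21,11
19,Gea2-GFP,Sec7-tagRFP,Gea2,Sec7,23.6,16.8,7,6
20,Sys1-iRFP,Imh1-EGFP,Sys1,Imh1,0.6,12.9,16,10
21,Sec7-tagRFP,Gga1-GFP,Sec7,Gga1,15.8,17.9,13,6
22,Sys1-iRFP,Apl6-GFP,Sys1,Apl6,5.8,27.8,13,11
23,Sec7-mRFP,Ypt32-GFP,Sec7,Ypt32,51.9,23.2,7,4
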