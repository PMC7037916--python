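no,compound_id,name,p_ec50,p_loec,composite,split,flag
1,PIP,Pipemidic acid,-4.59,4.80,-0.94,train,
2,CIN,Cinoxacin,-2.24,6.52,-0.17,test,
3,NOR,Norfloxacin,-3.64,7.67,-0.48,train,
4,BAL,Balofloxacin,-2.83,7.31,-0.28,test,
5,CIP,Ciprofloxacin,-3.45,7.85,-0.41,train,
6,DAN,Danofloxacin,-3.17,7.66,-0.35,train,
7,DIF,Difloxacin,-2.64,8.06,-0.17,test,
8,ENR,Enrofloxacin,-3.00,8.75,-0.23,train,
9,FLE,Fleroxacin,-3.46,6.77,-0.49,train,
10,GAT,Gatifloxacin,-3.16,8.28,-0.30,train,
11,LOM,Lomefloxacin,-3.26,7.54,-0.38,train,
12,MOX,Moxifloxacin,-0.32,8.89,0.53,train,
13,NAD,Nadifloxacin,-1.62,8.08,0.11,train,
14,OFL,Ofloxacin,-3.62,7.96,-0.45,train,
15,PAZ,Pazufloxacin,-3.52,8.54,-0.38,test,
16,RUF,Rufloxacin,-3.55,6.89,-0.51,train,
17,SAR,Sarafloxacin,-2.77,7.92,-0.22,train,
18,SPA,Sparfloxacin,-3.44,7.37,-0.44,test,
19,LEV,Levofloxacin,-3.62,7.75,-0.47,train,
20,ENO,Enoxacin,-3.58,7.08,-0.50,test,
21,PEF,Pefloxacin,-3.51,7.96,-0.42,train,
22,AMI,Amifloxacin,-4.39,8.00,-0.66,test,
23,BES,Besifloxacin,-2.43,7.50,-0.15,test,
24,CLI,Clinafloxacin,-3.08,7.19,-0.36,train,
25,GRE,Grepafloxacin,-2.81,7.47,-0.26,train,
26,MAR,Marbofloxacin,-4.26,8.46,-0.60,train,
27,ORB,Orbifloxacin,-2.67,7.51,-0.22,test,
28,SIT,Sitafloxacin,-2.69,7.28,-0.24,test,
29,TEM,Temafloxacin,-2.38,8.47,-0.07,train,
30,1-CH3-PAZ,1-CH3-PAZ,-0.98,8.05,0.29,train,
31,1-H-PAZ,1-H-PAZ,-1.27,7.67,0.18,train,
32,5-OH-PAZ,5-OH-PAZ,-4.87,8.38,-0.77,train,
33,5-F-PAZ,5-F-PAZ,-3.90,7.57,-0.56,train,
34,1-C2H3-5-F-PAZ,1-C2H3-5-F-PAZ,-1.14,7.13,0.18,train,
35,1-CO-5-OH-PAZ,1-CO-5-OH-PAZ,-3.39,7.72,-0.41,train,
36,1-CO-5-F-PAZ,1-CO-5-F-PAZ,-2.42,7.14,-0.18,train,
37,7-OH-CIP,7-OH-CIP,-4.53,8.25,-0.69,train,
38,7-C2H5-CIP,7-C2H5-CIP,-2.85,7.98,-0.24,train,
39,7-CN-CIP,7-CN-CIP,-3.86,8.07,-0.51,train,
40,7-NO-CIP,7-NO-CIP,-3.66,8.14,-0.45,train,
41,7-OCH3-CIP,7-OCH3-CIP,-3.68,8.38,-0.44,train,
42,7-C2H3-CIP,7-C2H3-CIP,-2.94,8.34,-0.24,train,
43,7-COOH-CIP,7-COOH-CIP,-4.70,8.31,-0.73,train,
44,9-F-NAD,9-F-NAD,-1.73,8.33,0.10,train,
45,9-Cl-NAD,9-Cl-NAD,-1.53,8.32,0.15,train,
46,9-Br-NAD,9-Br-NAD,-1.52,8.28,0.15,train,
47,2-C2H3-NAD,2-C2H3-NAD,-1.02,8.32,0.29,train,
48,2-C2H3-9-F-NAD,2-C2H3-9-F-NAD,-1.13,8.18,0.25,train,
49,2-C2H-9-F-NAD,2-C2H-9-F-NAD,-1.57,8.29,0.14,train,
50,2-C2H3-9-Cl-NAD,2-C2H3-9-Cl-NAD,-1.37,8.29,-0.17,train,inconsistent
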