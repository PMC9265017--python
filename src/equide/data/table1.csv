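id,source,kind,cp,cf,nfe,ee,dcp,dcf,dnfe,dee,de_obs,pred_ns,pred_zk
1,Lindsey et al.,mixed diet,13.7,19.3,58.8,3.6,10.6,2.5,45.8,1.9,2823,2811,2840
2,Lindsey et al.,mixed diet,11.9,21.6,58.2,3.8,7.8,6.2,37.0,1.3,2415,2709,2754
3,Lindsey et al.,mixed diet,7.8,26.9,58.4,2.3,4.4,10.5,38.7,0.2,2392,2351,2424
4,Lindsey et al.,mixed diet,11.9,29.2,50.9,3.4,7.5,11.8,26.5,0.8,2183,2348,2407
5,Lindsey et al.,mixed diet,7.2,26.5,59.4,2.7,4.5,0.0,50.7,0.6,2428,2395,2474
6,Lindsey et al.,mixed diet,7.3,26.6,59.3,2.5,5.3,0.0,50.8,0.7,2495,2380,2458
7,Lindsey et al.,mixed diet,6.7,29.4,57.6,2.0,3.0,12.8,31.0,0.4,2116,2223,2309
8,Lindsey et al.,mixed diet,14.8,29.3,53.5,2.3,9.6,13.1,30.8,0.2,2487,2486,2556
9,Lindsey et al.,mixed diet,13.3,29.4,54.8,2.1,7.9,12.8,31.8,0.0,2392,2444,2521
10,Lindsey et al.,mixed diet,12.1,28.3,50.4,3.4,8.2,12.1,30.0,1.1,2402,2344,2393
11,Lindsey et al.,mixed diet,11.8,28.3,51.5,3.4,8.2,10.6,26.2,1.4,2200,2370,2425
12,Lindsey et al.,mixed diet,11.7,27.4,52.2,3.2,8.2,11.0,30.7,0.6,2342,2385,2435
13,Lindsey et al.,mixed diet,11.3,27.3,53.2,3.2,7.4,8.9,27.0,0.6,2032,2405,2460
14,Lindsey et al.,mixed diet,7.5,29.9,55.0,2.7,4.4,11.5,28.1,0.5,2027,2225,2306
15,Lindsey et al.,mixed diet,6.3,31.9,54.2,2.3,2.5,14.6,29.1,0.5,2109,2082,2170
16,Lindsey et al.,mixed diet,10.4,29.8,51.8,3.0,6.5,11.2,25.5,0.9,2061,2271,2336
17,Lindsey et al.,mixed diet,8.7,28.2,54.4,2.9,5.1,9.8,32.5,0.5,2161,2289,2354
18,Lindsey et al.,mixed diet,8.6,27.6,55.5,3.0,4.8,10.4,28.5,0.5,2016,2339,2408
19,Hintz and Loy,mixed diet,17.7,15.8,54.2,4.0,13.3,5.3,43.1,2.8,3085,2899,2799
20,Hintz and Loy,mixed diet,17.0,16.5,54.7,3.6,12.9,5.8,43.3,2.3,3052,2843,2752
21,Martin-Rosset and Dulphy,mixed feed,13.6,3.5,75.5,3.1,,,,,3499,3496,3429
22,Martin-Rosset and Dulphy,mixed feed,21.6,6.0,64.2,2.6,,,,,3531,3400,3285
23,Parkins et al.,mixed diet,11.3,22.7,55.7,2.0,8.1,5.4,32.3,1.4,2182,2418,2387
24,Saastamoinen and Sarkijarvi,mixed diet,10.0,27.5,54.3,2.8,6.1,12.2,34.1,1.6,2509,2337,2342
25,Saastamoinen and Sarkijarvi,mixed diet,11.0,26.1,53.0,4.2,7.1,11.5,32.8,2.9,2598,2479,2462
26,Saastamoinen and Sarkijarvi,mixed diet,11.0,26.2,52.9,4.1,7.2,12.1,33.6,2.8,2667,2466,2450
27,Smolders et al.,mixed feed,20.6,11.5,54.0,5.3,,,,,3446,3178,3038
28,Smolders et al.,mixed feed,18.0,12.0,55.0,2.2,,,,,3137,2806,2673
29,Smolders et al.,mixed feed,16.7,10.9,59.8,3.8,,,,,3379,3074,2966
30,Smolders et al.,mixed feed,15.6,12.4,57.5,3.9,,,,,3097,2934,2821
31,Smolders et al.,mixed feed,9.2,20.7,59.2,2.6,,,,,2484,2514,2487
32,Smolders et al.,mixed feed,20.5,7.5,59.1,4.5,,,,,3446,3318,3177
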