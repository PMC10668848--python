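individual,training,testing_day1,testing_day2
1,2959,2838,2652
2,2000,2845,2688
3,2670,2501,3000
4,3000,3000,2986
5,3000,3000,3000
6,3000,3000,2656
7,3000,2127,2644
8,3000,2920,2952
9,3000,3000,2645
10,2923,2787,2708
11,3000,1181,1627
12,2948,3000,2929
13,3000,2797,2817
14,2930,2910,2973
15,2990,2276,2457
16,3000,2839,2977
17,2966,3000,2000
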