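window,group,heading_index,heading,count,percent
1,control,1,I,440,2.98
1,risk,1,I,73,3.52
2,control,1,I,638,4.31
2,risk,1,I,115,5.55
3,control,1,I,944,6.38
3,risk,1,I,157,7.58
4,control,1,I,1352,9.14
4,risk,1,I,259,12.50
5,control,1,I,1816,12.28
5,risk,1,I,346,16.70
1,control,2,II,28,0.19
1,risk,2,II,1,0.05
2,control,2,II,45,0.30
2,risk,2,II,5,0.24
3,control,2,II,67,0.45
3,risk,2,II,7,0.34
4,control,2,II,131,0.89
4,risk,2,II,10,0.48
5,control,2,II,194,1.31
5,risk,2,II,17,0.82
1,control,3,III,142,0.96
1,risk,3,III,22,1.06
2,control,3,III,190,1.28
2,risk,3,III,25,1.21
3,control,3,III,269,1.82
3,risk,3,III,47,2.27
4,control,3,III,417,2.82
4,risk,3,III,78,3.76
5,control,3,III,577,3.90
5,risk,3,III,100,4.83
1,control,4,IV,724,4.90
1,risk,4,IV,165,7.96
2,control,4,IV,994,6.72
2,risk,4,IV,252,12.16
3,control,4,IV,1331,9.00
3,risk,4,IV,340,16.41
4,control,4,IV,1740,11.77
4,risk,4,IV,420,20.27
5,control,4,IV,2223,15.03
5,risk,4,IV,483,23.31
1,control,5,VI,230,1.56
1,risk,5,VI,60,2.90
2,control,5,VI,324,2.19
2,risk,5,VI,79,3.81
3,control,5,VI,454,3.07
3,risk,5,VI,104,5.02
4,control,5,VI,599,4.05
4,risk,5,VI,134,6.47
5,control,5,VI,858,5.80
5,risk,5,VI,166,8.01
1,control,6,"VII,VIII",16,0.11
1,risk,6,"VII,VIII",1,0.05
2,control,6,"VII,VIII",26,0.18
2,risk,6,"VII,VIII",1,0.05
3,control,6,"VII,VIII",46,0.31
3,risk,6,"VII,VIII",3,0.14
4,control,6,"VII,VIII",102,0.69
4,risk,6,"VII,VIII",9,0.43
5,control,6,"VII,VIII",184,1.24
5,risk,6,"VII,VIII",9,0.43
1,control,7,IX,748,5.06
1,risk,7,IX,120,5.79
2,control,7,IX,1022,6.91
2,risk,7,IX,163,7.87
3,control,7,IX,1347,9.11
3,risk,7,IX,220,10.62
4,control,7,IX,1766,11.94
4,risk,7,IX,291,14.04
5,control,7,IX,2329,15.75
5,risk,7,IX,426,20.56
1,control,8,X,548,3.71
1,risk,8,X,53,2.56
2,control,8,X,700,4.73
2,risk,8,X,88,4.25
3,control,8,X,898,6.07
3,risk,8,X,142,6.85
4,control,8,X,1199,8.11
4,risk,8,X,216,10.42
5,control,8,X,1533,10.37
5,risk,8,X,282,13.61
1,control,9,XI,534,3.61
1,risk,9,XI,154,7.43
2,control,9,XI,790,5.34
2,risk,9,XI,227,10.96
3,control,9,XI,1145,7.74
3,risk,9,XI,297,14.33
4,control,9,XI,1650,11.16
4,risk,9,XI,384,18.53
5,control,9,XI,2347,15.87
5,risk,9,XI,502,24.23
1,control,10,XII,188,1.27
1,risk,10,XII,37,1.79
2,control,10,XII,257,1.74
2,risk,10,XII,51,2.46
3,control,10,XII,345,2.33
3,risk,10,XII,71,3.43
4,control,10,XII,521,3.52
4,risk,10,XII,113,5.45
5,control,10,XII,755,5.11
5,risk,10,XII,166,8.01
1,control,11,XIII,428,2.89
1,risk,11,XIII,138,6.66
2,control,11,XIII,699,4.73
2,risk,11,XIII,171,8.25
3,control,11,XIII,1004,6.79
3,risk,11,XIII,256,12.36
4,control,11,XIII,1412,9.55
4,risk,11,XIII,361,17.42
5,control,11,XIII,2037,13.78
5,risk,11,XIII,471,22.73
1,control,12,XIV,444,3.00
1,risk,12,XIV,57,2.75
2,control,12,XIV,598,4.04
2,risk,12,XIV,86,4.15
3,control,12,XIV,844,5.71
3,risk,12,XIV,113,5.45
4,control,12,XIV,1098,7.43
4,risk,12,XIV,183,8.83
5,control,12,XIV,1389,9.39
5,risk,12,XIV,237,11.44
1,control,13,XV,90,0.61
1,risk,13,XV,8,0.39
2,control,13,XV,152,1.03
2,risk,13,XV,15,0.72
3,control,13,XV,216,1.46
3,risk,13,XV,45,2.17
4,control,13,XV,386,2.61
4,risk,13,XV,85,4.10
5,control,13,XV,617,4.17
5,risk,13,XV,114,5.50
1,control,14,XVIII,2079,14.06
1,risk,14,XVIII,547,26.40
2,control,14,XVIII,2804,18.96
2,risk,14,XVIII,759,36.63
3,control,14,XVIII,3660,24.75
3,risk,14,XVIII,978,47.20
4,control,14,XVIII,4690,31.72
4,risk,14,XVIII,1125,54.30
5,control,14,XVIII,6041,40.86
5,risk,14,XVIII,1311,63.27
1,control,15,XIX,1677,11.34
1,risk,15,XIX,574,27.70
2,control,15,XIX,2175,14.71
2,risk,15,XIX,729,35.18
3,control,15,XIX,2934,19.84
3,risk,15,XIX,946,45.66
4,control,15,XIX,4023,27.21
4,risk,15,XIX,1095,52.85
5,control,15,XIX,5205,35.20
5,risk,15,XIX,1254,60.52
1,control,16,XX,1315,8.89
1,risk,16,XX,495,23.89
2,control,16,XX,1867,12.63
2,risk,16,XX,668,32.24
3,control,16,XX,2727,18.44
3,risk,16,XX,872,42.08
4,control,16,XX,3912,26.46
4,risk,16,XX,1064,51.35
5,control,16,XX,5169,34.96
5,risk,16,XX,1260,60.81
1,control,17,XXI,3013,20.38
1,risk,17,XXI,814,39.29
2,control,17,XXI,3911,26.45
2,risk,17,XXI,1010,48.75
3,control,17,XXI,5053,34.17
3,risk,17,XXI,1231,59.41
4,control,17,XXI,6476,43.80
4,risk,17,XXI,1470,70.95
5,control,17,XXI,7916,53.54
5,risk,17,XXI,1624,78.38
1,control,18,XXII,989,6.69
1,risk,18,XXII,455,21.96
2,control,18,XXII,1391,9.41
2,risk,18,XXII,595,28.72
3,control,18,XXII,2086,14.11
3,risk,18,XXII,808,39.00
4,control,18,XXII,3070,20.76
4,risk,18,XXII,984,47.49
5,control,18,XXII,4106,27.77
5,risk,18,XXII,1165,56.23
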