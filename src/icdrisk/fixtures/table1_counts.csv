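window,group,bin,count,percent
1,control,0,8112,54.86
1,control,1-2,2914,19.71
1,control,3-5,1641,11.10
1,control,6-10,1317,8.91
1,control,11-20,657,4.44
1,control,>20,145,0.98
1,risk,0,557,26.88
1,risk,1-2,500,24.13
1,risk,3-5,319,15.40
1,risk,6-10,356,17.18
1,risk,11-20,247,11.92
1,risk,>20,93,4.49
2,control,0,6909,46.73
2,control,1-2,2925,19.78
2,control,3-5,1870,12.65
2,control,6-10,1666,11.27
2,control,11-20,1028,6.95
2,control,>20,388,2.62
2,risk,0,413,19.93
2,risk,1-2,430,20.75
2,risk,3-5,305,14.72
2,risk,6-10,315,15.20
2,risk,11-20,366,17.66
2,risk,>20,243,11.73
3,control,0,5545,37.50
3,control,1-2,2881,19.48
3,control,3-5,2044,13.82
3,control,6-10,1999,13.52
3,control,11-20,1499,10.14
3,control,>20,818,5.53
3,risk,0,250,12.07
3,risk,1-2,365,17.62
3,risk,3-5,277,13.37
3,risk,6-10,332,16.02
3,risk,11-20,345,16.65
3,risk,>20,503,24.28
4,control,0,3992,27.00
4,control,1-2,2733,18.48
4,control,3-5,2213,14.97
4,control,6-10,2286,15.46
4,control,11-20,2089,14.13
4,control,>20,1473,9.96
4,risk,0,162,7.82
4,risk,1-2,238,11.49
4,risk,3-5,254,12.26
4,risk,6-10,336,16.22
4,risk,11-20,386,18.63
4,risk,>20,696,33.59
5,control,0,2501,16.91
5,control,1-2,2517,17.02
5,control,3-5,2379,16.09
5,control,6-10,2532,17.12
5,control,11-20,2338,15.81
5,control,>20,2519,17.04
5,risk,0,85,4.10
5,risk,1-2,179,8.64
5,risk,3-5,216,10.42
5,risk,6-10,267,12.89
5,risk,11-20,383,18.48
5,risk,>20,942,45.46
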