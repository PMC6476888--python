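id,substituent_code,hct116_wt,hct116_wt_sd,hct116_null,hct116_null_sd,nhdf,nhdf_sd
1,H,>25,,>25,,,
2a,2-OCH3,>25,,>25,,,
2b,3-OCH3,8.51,1.69,24.05,3.54,>25,
2c,4-OCH3,>25,,>25,,,
2d,"2,5-OCH3",>25,,>25,,,
2e,"3,5-OCH3",>25,,>25,,>25,
2f,"3,4,5-OCH3",6.54,2.42,8.78,2.13,>25,
2g,2-OCH3-4-NO2,2.62,0.85,3.73,1.09,7.53,2.97
2h,2-OCH3-5-NO2,7.05,1.75,7.42,2.05,>25,
2i,2-OCH3-5-CF3,>25,,>25,,,
2j,2-OCH3-5-CH3,>25,,>25,,,
2k,2-OCH3-6-CH3,>25,,>25,,,
3a,2-CH3,>25,,>25,,,
3b,3-CH3,>25,,>25,,,
3c,4-CH3,>25,,>25,,,
3d,"2,5-CH3",>25,,>25,,,
3e,"2,6-CH3",>25,,>25,,,
3f,"3,5-CH3",19.31,1.68,>25,,>25,
3g,"2,4,6-CH3",>25,,>25,,,
3h,2-CH3-5-OCH3,11.65,3.81,>25,,>25,
3i,2-CH3-5-CF3,8.41,1.07,5.08,1.23,>25,
4a,2-F,>25,,>25,,,
4b,3-F,1.88,0.33,9.02,1.91,>25,
4c,4-F,2.49,0.61,5.01,1.12,>25,
4d,"2,4-F",6.55,0.83,11.41,1.92,>25,
4e,"2,5-F",4.76,0.76,15.05,6.75,>25,
4f,"2,6-F",>25,,>25,,,
4g,"3,4-F",3.04,0.06,5.88,0.50,22.21,1.61
4h,"3,5-F",1.79,0.44,2.24,0.30,9.87,0.66
4i,"2,3,4-F",4.28,0.66,4.43,0.66,>25,
4j,"2,4,5-F",1.87,0.35,4.75,0.05,24.52,0.03
4k,"2,4,6-F",>25,,>25,,,
4l,"3,4,5-F",1.19,0.31,1.42,0.25,10.04,0.54
4m,"2,3,5,6-F",11.95,0.92,>25,,>25,
4n,"2,3,4,5,6-F",11.59,0.74,17.54,0.76,>25,
4o,2-F-3-Cl,8.78,2.18,6.76,2.37,>25,
4p,2-F-3-CF3,6.50,1.16,5.45,1.72,24.44,2.51
4q,2-F-4-Cl,9.89,3.26,9.69,3.13,>25,
4r,2-F-4-Br,14.99,4.82,3.43,0.69,>25,
4s,2-F-5-Cl,8.66,1.61,10.66,1.73,>25,
4t,2-F-5-Br,11.94,1.28,14.01,2.2,>25,
4u,2-F-5-CF3,10.05,2.61,7.45,1.74,>25,
4v,3-F-4-Br,10.86,2.69,12.43,1.11,>25,
4w,3-F-4-CF3,3.25,0.94,4.82,1.46,22.82,2.69
4x,3-F-5-CF3,9.01,0.45,>25,,24.12,2.02
4y,"2,3,5,6-F-4-Br",2.41,0.69,5.68,1.37,7.87,1.37
4z,"2,5-F-4-CF3",4.22,0.87,2.82,0.77,18.35,0.91
5a,2-Cl,16.49,2.25,22.44,3.58,>25,
5b,3-Cl,4.70,0.40,1.78,0.32,>25,
5c,4-Cl,9.62,0.75,9.41,0.78,>25,
5d,"2,3-Cl",4.66,0.58,8.25,0.64,>25,
5e,"2,4-Cl",1.95,0.50,6.06,1.13,>25,
5f,"2,5-Cl",7.45,0.85,7.19,1.15,>25,
5g,"2,6-Cl",>25,,>25,,,
5h,"3,4-Cl",5.15,0.50,4.74,0.82,>25,
5i,"3,5-Cl",2.32,0.26,2.89,0.38,11.47,0.88
5j,"2,4,5-Cl",3.00,0.24,6.21,0.66,20.19,0.79
5k,"2,4,6-Cl",19.37,1.27,>25,,>25,
5l,"3,4,5-Cl",1.31,0.15,2.86,0.33,7.01,0.42
5m,2-Cl-4-F,7.57,2.16,8.29,2.92,>25,
5n,2-Cl-4-Br,2.33,0.95,9.79,1.95,23.45,0.86
5o,2-Cl-4-CF3,4.92,1.32,5.41,1.11,13.18,1.97
5p,2-Cl-5-OCH3,24.10,2.58,19.31,2.09,>25,
5q,2-Cl-5-Br,4.18,1.49,5.40,2.04,>25,
5r,2-Cl-5-CF3,2.48,0.31,1.46,0.21,12.40,1.14
5s,3-Cl-4-F,6.87,2.48,0.83,0.31,>25,
5t,3-Cl-4-Br,12.35,0.79,12.58,0.69,>25,
5u,"2-Cl-3,5-CF3",0.72,0.28,2.72,0.63,16.30,1.28
5v,"2,6-Cl-4-CF3",>25,,>25,,,
6a,2-Br,22.51,3.62,>25,,>25,
6b,3-Br,9.19,0.98,8.73,0.89,15.21,2.48
6c,4-Br,5.25,0.67,11.01,0.97,>25,
6d,"2,4-Br",4.56,0.43,4.61,0.72,>25,
6e,"2,5-Br",5.24,0.28,5.85,0.61,>25,
6f,"2,6-Br",>25,,>25,,,
6g,"2,4,6-Br",>25,,>25,,,
6h,2-Br-4-Cl,9.54,2.71,13.23,2.3,>25,
6i,2-Br-4-CF3,3.58,1.25,2.19,0.67,18.42,1.23
6j,2-Br-5-F,7.78,1.37,5.83,1.06,>25,
6k,2-Br-5-CF3,8.18,1.72,7.15,1.96,22.23,0.83
6l,"2,6-Br-4-CF3",9.37,0.47,6.81,2.66,20.37,1.16
6m,"2,6-Br-3-Cl-4-F",>25,,>25,,,
7a,2-CF3,>25,,21.36,1.24,,
7b,3-CF3,6.25,0.47,1.39,0.29,>25,
7c,4-CF3,4.31,0.51,1.07,0.26,16.57,2.17
7d,"2,4-CF3",11.31,1.31,8.69,1.02,>25,
7e,"2,5-CF3",4.44,1.16,8.53,3.37,22.93,2.10
7f,"3,5-CF3",0.46,0.05,0.35,0.08,3.55,0.76
7g,2-CF3-4-F,>25,,>25,,,
7h,2-CF3-4-Cl,>25,,>25,,,
7i,2-CF3-4-Br,>25,,>25,,,
7j,2-CF3-4-NO2,2.04,0.71,4.74,1.68,12.55,1.32
7k,3-CF3-4-OCH3,>25,,>25,,,
7l,3-CF3-4-CH3,>25,,>25,,,
7m,3-CF3-4-F,11.96,3.68,14.49,4.53,>25,
7n,3-CF3-4-Cl,9.66,3.17,18.72,2.78,>25,
7o,3-CF3-4-Br,>25,,13.90,3.75,>25,
7p,3-CF3-4-NO2,1.64,0.47,1.39,0.44,9.68,1.49
8a,2-NO2,23.32,3.77,>25,,22.71,2.71
8b,3-NO2,6.82,1.17,3.10,0.63,>25,
8c,4-NO2,0.41,0.05,0.69,0.09,12.30,1.49
8d,2-NO2-4-CF3,>25,,>25,,,
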