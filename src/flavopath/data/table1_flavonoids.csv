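sample_id,group,Y_HY,Y_HY_sd,Y_HY_letters,Y_LU,Y_LU_sd,Y_LU_letters,Y_KP,Y_KP_sd,Y_KP_letters,Y_QI,Y_QI_sd,Y_QI_letters,Y_C,Y_C_sd,Y_C_letters,Y_RU,Y_RU_sd,Y_RU_letters,Y_CA,Y_CA_sd,Y_CA_letters,Y_QU,Y_QU_sd,Y_QU_letters,Y_HE,Y_HE_sd,Y_HE_letters,Y_AP,Y_AP_sd,Y_AP_letters,Y_PH,Y_PH_sd,Y_PH_letters,Y_PG,Y_PG_sd,Y_PG_letters,Y_CGT,Y_CGT_sd,Y_CGT_letters,Y_CGC,Y_CGC_sd,Y_CGC_letters,Y_CSA,Y_CSA_sd,Y_CSA_letters
A1,A,22.88,0.06,b,2.34,0.06,e,1.89,0.21,d,28.66,0.36,e,7.85,0.02,f,6.42,0.38,j,9.80,0.16,f,3.02,0.28,c,3.46,0.12,i,5.04,0.20,a,6.77,0.13,cd,7.52,0.09,b,12.13,0.22,a,11.58,0.46,a,7.54,0.14,e
A2,A,27.84,0.38,a,1.92,0.08,f,2.10,0.02,c,36.28,0.53,b,9.82,0.11,d,6.78,0.19,h,14.54,0.14,c,2.51,0.06,d,4.23,0.06,f,3.01,0.09,de,6.53,0.07,de,8.15,0.10,a,11.43,0.08,b,9.90,0.19,cd,8.22,0.11,c
A3,A,18.56,0.19,c,1.92,0.01,f,1.89,0.02,d,31.95,0.34,d,6.86,0.10,g,6.94,0.17,h,11.07,0.08,d,2.43,0.08,d,3.81,0.17,gh,4.34,0.10,b,7.50,0.20,b,7.34,0.11,b,10.03,0.13,d,10.56,0.15,bc,8.70,0.02,b
A4,A,8.91,0.59,m,3.32,0.32,b,1.49,0.45,g,34.36,2.31,c,6.45,0.17,h,8.83,0.06,e,16.50,0.45,b,4.13,0.36,b,3.58,0.08,i,3.77,0.10,c,8.05,0.11,a,6.85,0.09,c,10.52,0.21,c,9.97,0.40,cd,8.73,0.17,b
A5,A,14.54,0.15,f,3.80,0.28,a,1.79,0.02,e,33.62,0.38,c,7.95,0.14,f,5.62,0.28,k,21.06,0.21,a,5.16,0.38,a,3.49,0.18,i,3.62,0.12,c,7.38,0.08,b,6.91,0.09,c,12.02,0.19,a,9.31,0.17,e,8.98,0.14,b
A6,A,13.58,0.02,g,2.79,0.25,d,1.97,0.04,c,45.13,0.06,a,8.79,0.18,e,6.90,0.02,h,16.68,0.37,b,3.12,0.17,c,4.50,0.05,e,3.57,0.07,c,6.39,0.22,e,6.41,0.17,d,10.32,0.27,cd,9.71,0.14,cd,9.00,0.13,b
B1,B,10.94,0.11,l,3.11,0.06,c,1.79,0.01,e,19.97,0.23,h,7.88,0.02,f,6.42,0.38,j,5.39,0.28,k,1.26,0.04,g,5.08,0.05,c,2.81,0.14,e,6.55,0.18,d,7.31,0.18,b,8.32,0.20,fg,10.15,0.09,c,8.83,0.24,b
B2,B,10.80,0.08,l,3.57,0.13,a,2.99,0.04,a,20.81,0.74,h,13.55,0.62,a,7.67,0.14,g,6.63,0.08,i,1.59,0.14,ef,4.35,0.10,f,3.10,0.18,d,6.89,0.27,c,6.95,0.26,c,9.48,0.22,e,8.36,0.36,fg,7.89,0.16,d
B3,B,8.87,0.62,m,1.37,0.02,j,1.43,0.02,g,23.63,2.23,g,11.64,0.13,b,5.79,0.06,k,7.35,0.21,h,1.77,0.04,ef,3.70,0.07,h,2.54,0.09,f,6.94,0.08,c,6.97,0.17,c,10.13,0.20,cd,10.11,0.28,c,9.92,0.25,a
B4,B,8.24,0.02,m,3.06,0.08,c,1.66,0.09,f,22.85,0.15,g,10.63,0.57,c,4.73,0.21,l,6.59,0.16,i,1.99,0.19,e,4.32,0.18,f,2.51,0.12,f,6.72,0.12,cd,6.97,0.13,c,9.44,0.10,e,10.10,0.43,c,8.17,0.15,cd
B5,B,14.21,0.19,f,1.93,0.11,f,1.34,0.04,h,26.06,0.28,f,10.96,0.23,c,6.49,0.64,i,6.08,0.91,j,1.56,0.21,f,4.53,0.09,e,3.72,0.12,c,5.82,0.22,f,5.38,0.21,e,9.66,0.39,e,9.57,0.44,d,7.38,0.20,e
C1,C,12.45,0.34,i,1.01,0.23,m,1.62,0.06,f,12.57,0.25,m,5.91,0.73,h,10.22,0.12,c,3.00,0.22,n,2.49,0.42,d,4.95,0.16,cd,2.99,0.26,de,5.01,0.16,hi,4.83,0.07,fg,6.54,0.23,i,7.44,0.26,h,6.04,0.18,f
C2,C,13.82,0.06,g,1.61,0.02,h,1.30,0.13,h,14.16,0.04,kl,8.55,0.02,e,10.10,0.02,c,7.40,0.12,h,0.41,0.11,k,5.31,0.21,bc,2.03,0.27,h,4.38,0.23,j,5.23,0.12,ef,7.52,0.11,h,7.97,0.16,g,5.64,0.02,g
C3,C,13.13,0.87,h,0.83,0.11,n,2.64,0.11,b,13.58,0.36,l,7.08,0.08,g,10.47,0.36,c,9.56,0.25,f,0.74,0.02,j,4.71,0.14,d,2.21,0.11,g,4.67,0.22,i,5.04,0.19,f,8.55,0.29,f,7.69,0.17,gh,8.86,0.19,b
C4,C,14.64,0.17,f,1.26,0.04,k,1.73,0.04,e,15.21,0.21,j,6.32,0.06,h,8.79,0.19,e,3.18,0.10,m,3.87,0.13,b,4.79,0.23,d,1.69,0.13,ij,5.47,0.18,g,4.40,0.11,h,8.06,0.14,g,8.51,0.12,f,5.63,0.15,g
C5,C,14.22,0.89,f,1.71,0.09,g,1.33,0.04,h,14.75,0.19,k,9.83,0.13,d,13.07,0.11,a,4.07,0.12,l,0.39,0.06,k,4.93,0.12,cd,2.21,0.11,g,3.70,0.21,l,4.28,0.14,i,7.43,0.27,h,6.40,0.29,i,4.89,0.23,il
C6,C,11.85,0.30,k,1.83,0.02,f,0.98,0.02,i,13.47,0.34,l,8.41,0.02,e,11.72,0.15,b,5.00,0.03,k,4.11,0.34,b,3.91,0.20,g,2.26,0.11,g,4.01,0.19,k,4.08,0.16,ij,8.53,0.25,f,7.50,0.28,gh,5.36,0.11,gh
C7,C,12.86,0.19,i,0.76,0.04,n,2.46,0.04,bc,12.27,0.68,m,5.44,0.11,i,9.87,0.02,d,9.83,0.15,f,0.44,0.06,k,5.35,0.18,bc,2.38,0.14,fg,4.06,0.09,k,4.38,0.04,h,7.13,0.18,h,8.44,0.14,fg,5.10,0.15,i
D1,D,16.73,0.23,d,0.29,0.02,o,1.85,0.04,d,16.83,0.13,i,9.59,0.12,d,8.31,0.02,f,8.19,0.14,g,1.83,0.04,ef,5.87,0.22,a,1.76,0.22,i,5.15,0.21,h,4.74,0.09,g,10.12,0.40,cd,10.68,0.43,b,5.96,0.32,f
D2,D,18.56,0.23,c,1.56,0.02,hi,1.89,0.15,d,16.65,0.38,i,8.55,0.06,e,9.10,0.17,e,7.58,0.15,h,0.26,0.03,l,4.54,0.25,e,1.30,0.25,j,4.29,0.24,jk,4.56,0.15,gh,8.37,0.31,fg,7.82,0.36,gh,4.63,0.12,l
D3,D,15.69,0.08,e,0.45,0.02,o,1.81,0.04,d,15.35,0.11,j,7.46,0.18,g,7.22,0.04,gh,8.34,0.15,g,0.29,0.02,l,5.50,0.15,b,2.18,0.14,g,4.76,0.09,i,5.20,0.12,ef,9.63,0.27,e,9.84,0.27,cd,4.58,0.22,l
E1,E,15.90,0.21,de,1.48,0.42,i,0.83,0.04,j,10.29,0.34,o,5.34,0.04,i,6.54,0.13,i,10.58,0.37,e,0.83,0.09,i,3.88,0.31,gh,2.13,0.09,g,3.23,0.10,m,3.83,0.26,j,5.47,0.18,j,5.00,0.20,j,3.49,0.14,n
E2,E,14.25,1.19,f,1.89,0.04,f,1.85,0.12,d,11.13,0.12,n,9.66,0.71,d,8.86,0.49,e,11.37,0.13,d,0.68,0.13,j,5.42,0.10,b,2.03,0.12,h,4.26,0.13,jk,3.51,0.12,k,6.16,0.20,i,4.48,0.17,k,4.16,0.17,m
E3,E,6.03,0.08,n,1.05,0.08,m,0.97,0.04,i,9.60,0.42,o,6.44,0.16,h,6.99,0.25,h,2.64,0.30,n,1.16,0.11,gh,3.82,0.24,gh,1.55,0.10,ij,3.66,0.11,l,4.02,0.14,ij,5.34,0.15,j,4.55,0.18,k,4.60,0.15,l
E4,E,14.30,0.11,f,1.16,0.06,l,0.66,0.04,k,7.55,0.42,p,4.65,0.16,j,4.51,0.04,l,2.64,0.28,n,0.98,0.06,h,3.48,0.26,i,1.39,0.20,j,3.31,0.16,m,3.10,0.13,l,6.35,0.16,i,6.46,0.32,i,5.19,0.13,h
E5,E,12.44,0.06,j,2.16,0.08,e,1.11,0.06,i,8.61,0.02,p,9.59,0.12,d,3.28,0.19,m,3.86,0.06,l,1.01,0.07,gh,2.69,0.13,j,1.33,0.12,j,3.47,0.22,m,3.27,0.09,kl,5.45,0.21,j,6.23,0.15,i,4.64,0.25,l
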