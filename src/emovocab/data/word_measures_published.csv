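english,german,pf_4_5,pf_6_7,pf_8_9,pf_10_11,pf_adult,conv_4_5,conv_6_7,conv_8_9,conv_10_11,input_frequency,specificity
Fear,Angst,3.73,5.59,7.50,7.20,8.90,0.47,0.75,0.69,0.85,323,0.51
Anger,Ärger,0.00,0.00,0.00,1.72,3.49,0.00,0.00,0.00,0.59,257,0.31
Excited,aufgeregt,0.83,0.00,0.65,0.34,0.78,0.18,0.00,0.18,0.61,100,0.19
Enthusiastic,begeistert,0.00,0.00,0.00,0.17,0.78,0.00,0.00,0.00,0.51,21,0.19
Avid,begierig,0.00,0.17,0.00,0.17,0.78,0.00,1.00,0.00,1.00,17,0.12
Worried,besorgt,0.21,0.17,0.00,1.72,3.88,0.54,0.54,0.00,0.54,49,0.29
Jealous,eifersüchtig,0.00,0.00,0.16,0.69,0.19,0.00,0.00,1.00,1.00,1,0.05
Lonely,einsam,0.62,0.51,0.98,1.72,3.10,0.57,0.18,0.68,0.65,21,0.32
Disgust,Ekel,1.04,1.02,2.12,3.26,3.88,1.00,1.00,1.00,1.00,65,0.10
Disappointed,enttäuscht,0.00,0.00,0.49,1.37,4.65,0.00,0.00,0.50,0.43,16,0.35
Scared,erschrocken,0.41,2.03,1.63,0.17,0.78,-0.17,0.48,0.11,0.46,131,0.21
Joy,Freude,2.28,1.19,1.79,5.32,8.14,0.85,0.79,0.98,0.90,316,0.74
Glad,froh,3.11,0.51,0.00,0.51,0.00,0.00,0.00,0.00,0.00,7,
Happy,fröhlich,8.30,17.29,18.92,7.89,0.00,0.00,0.00,0.00,0.00,22,
Frustrated,frustiert,0.00,0.00,0.00,0.17,0.78,0.00,0.00,0.00,1.00,2,0.12
Safe,geborgen,0.00,0.00,0.33,1.72,1.94,0.00,0.00,0.69,1.00,0,0.16
Annoyed,genervt,0.00,0.00,0.00,0.34,0.97,0.00,0.00,0.00,0.69,31,0.14
Happy,glücklich,4.76,8.31,5.71,13.21,7.17,0.89,0.91,0.94,0.97,418,0.89
Horror,Grusel,0.00,0.68,0.00,0.34,0.00,0.00,0.00,0.00,0.00,17,
Sorrow,Kummer,0.62,0.00,0.33,0.00,0.39,0.33,0.00,-0.11,0.00,6,0.11
Love,Liebe,0.00,0.00,0.00,0.34,0.78,0.00,0.00,0.00,0.65,1349,0.16
Unspecific negative,unspezifisch negativ,20.12,2.71,4.40,2.74,0.58,0.38,0.36,0.33,0.33,619,0.16
Envious,neidisch,0.00,0.00,0.82,1.54,4.26,0.00,0.00,0.73,1.00,19,0.07
Embarrassed,peinlich,0.00,0.85,1.63,2.57,2.33,0.00,1.00,1.00,1.00,35,0.16
Unspecific positive,unspezifisch positiv,18.88,8.14,6.36,1.89,0.39,0.40,0.47,0.53,0.65,9092,0.11
Remorse,Reue,0.00,0.00,0.16,0.34,1.94,0.00,0.00,0.73,1.00,2,0.24
Angry,sauer,0.62,0.85,1.14,2.23,0.39,0.73,0.73,0.50,0.58,197,0.08
Shame,Scham,0.00,0.00,0.16,1.20,2.71,0.00,0.00,0.73,1.00,13,0.28
Guilty,schuldig,0.00,0.00,0.49,1.37,3.29,0.00,0.00,0.83,0.84,14,0.36
Longing,Sehnsucht,0.00,0.00,0.00,0.00,1.36,0.00,0.00,0.00,0.00,6,0.20
Proud,stolz,0.00,0.00,0.49,0.69,1.74,0.00,0.00,0.73,0.73,33,0.16
Sad,traurig,31.12,43.22,34.26,28.47,12.40,0.86,0.91,0.91,0.87,233,1.10
Surprised,überrascht,0.41,0.51,0.65,1.20,3.68,0.42,0.35,0.81,0.73,29,0.17
Unhappy,unglücklich,0.62,0.17,0.33,0.17,0.19,0.55,-0.05,-0.08,-0.05,39,0.05
Desperate,verzweifelt,0.00,0.17,0.00,0.17,0.58,0.00,0.55,0.00,-0.10,13,0.16
Anticipation,Vorfreude,0.00,0.00,0.00,0.34,0.78,0.00,0.00,0.00,0.73,0,0.16
Furious,wütend,2.28,5.59,7.99,5.15,2.33,0.84,0.83,0.64,0.65,11,0.27
Satisfied,zufrieden,0.00,0.00,0.00,0.34,2.71,0.00,0.00,0.00,0.69,41,0.15
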