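variant,induction,row_type,gamma_col,label
1,PAC,Pulse,0.8,S-F
1,PAC,Pulse,1,S-F
1,PAC,Pulse,1.2,S-F
1,PAC,Pulse,1.4/1.5,S-F*
1,PAC,Pulse,1.7,S-F*
1,PAC,Pulse,2,S-F*
1,PAC,ANS tone change,0.8,S-F
1,PAC,ANS tone change,1,S-F
1,PAC,ANS tone change,1.2,S-F
1,PAC,ANS tone change,1.4/1.5,S-F
1,PAC,ANS tone change,1.7,S-F*
1,PAC,ANS tone change,2,-
1,PVC,Pulse,0.8,-
1,PVC,Pulse,1,-
1,PVC,Pulse,1.2,-
1,PVC,Pulse,1.4/1.5,F-S*
1,PVC,Pulse,1.7,F-S*
1,PVC,Pulse,2,F-S*
1,PVC,ANS tone change,0.8,-
1,PVC,ANS tone change,1,-
1,PVC,ANS tone change,1.2,-
1,PVC,ANS tone change,1.4/1.5,-
1,PVC,ANS tone change,1.7,-
1,PVC,ANS tone change,2,-
1,PJC,ANS tone change,0.8,F-S
1,PJC,ANS tone change,1,F-S
1,PJC,ANS tone change,1.2,F-S
1,PJC,ANS tone change,1.4/1.5,F-S
1,PJC,ANS tone change,1.7,-
1,PJC,ANS tone change,2,-
2,PAC,Pulse,0.8,S-F
2,PAC,Pulse,1,S-F
2,PAC,Pulse,1.2,S-F
2,PAC,Pulse,1.4/1.5,S-F*
2,PAC,Pulse,1.7,-
2,PAC,Pulse,2,-
2,PAC,ANS tone change,0.8,S-F
2,PAC,ANS tone change,1,S-F
2,PAC,ANS tone change,1.2,S-F
2,PAC,ANS tone change,1.4/1.5,S-F*
2,PAC,ANS tone change,1.7,-
2,PAC,ANS tone change,2,-
2,PVC,Pulse,0.8,-
2,PVC,Pulse,1,F-S
2,PVC,Pulse,1.2,F-S
2,PVC,Pulse,1.4/1.5,F-S*
2,PVC,Pulse,1.7,F-S*
2,PVC,Pulse,2,F-S*
2,PVC,ANS tone change,0.8,F-S
2,PVC,ANS tone change,1,F-S
2,PVC,ANS tone change,1.2,F-S
2,PVC,ANS tone change,1.4/1.5,F-S*
2,PVC,ANS tone change,1.7,-
2,PVC,ANS tone change,2,-
2,PJC,ANS tone change,0.8,F-S
2,PJC,ANS tone change,1,F-S
2,PJC,ANS tone change,1.2,F-S
2,PJC,ANS tone change,1.4/1.5,F-S*
2,PJC,ANS tone change,1.7,-
2,PJC,ANS tone change,2,-
3,PAC,Pulse,0.8,S-F
3,PAC,Pulse,1,S-F
3,PAC,Pulse,1.2,S-F
3,PAC,Pulse,1.4/1.5,S-F*
3,PAC,Pulse,1.7,-
3,PAC,Pulse,2,-
3,PAC,ANS tone change,0.8,S-F
3,PAC,ANS tone change,1,S-F
3,PAC,ANS tone change,1.2,S-F
3,PAC,ANS tone change,1.4/1.5,S-F
3,PAC,ANS tone change,1.7,S-F*
3,PAC,ANS tone change,2,-
3,PVC,Pulse,0.8,S-F
3,PVC,Pulse,1,S-F
3,PVC,Pulse,1.2,S-F
3,PVC,Pulse,1.4/1.5,S-F*
3,PVC,Pulse,1.7,F-S*
3,PVC,Pulse,2,F-S*
3,PVC,ANS tone change,0.8,S-F
3,PVC,ANS tone change,1,S-F
3,PVC,ANS tone change,1.2,S-F
3,PVC,ANS tone change,1.4/1.5,S-F
3,PVC,ANS tone change,1.7,S-F*
3,PVC,ANS tone change,2,-
3,PJC,ANS tone change,0.8,-
3,PJC,ANS tone change,1,-
3,PJC,ANS tone change,1.2,-
3,PJC,ANS tone change,1.4/1.5,-
3,PJC,ANS tone change,1.7,-
3,PJC,ANS tone change,2,-
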