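station,season,score,label
1,spring,39.23,Relatively bad
1,summer,32.18,Relatively bad
1,fall,33.17,Relatively bad
1,winter,33.83,Relatively bad
1,mean,34.7,Relatively bad
2,spring,36.56,Relatively bad
2,summer,32.03,Relatively bad
2,fall,32.52,Relatively bad
2,winter,34.37,Relatively bad
2,mean,33.9,Relatively bad
3,spring,36.83,Relatively bad
3,summer,31.87,Relatively bad
3,fall,32.76,Relatively bad
3,winter,34.44,Relatively bad
3,mean,34,Relatively bad
4,spring,21.92,Bad
4,summer,19.27,Bad
4,fall,20.9,Bad
4,winter,20.53,Bad
4,mean,20.7,Bad
5,spring,37.4,Relatively bad
5,summer,32.34,Relatively bad
5,fall,31.55,Relatively bad
5,winter,34.04,Relatively bad
5,mean,33.8,Relatively bad
mean,spring,34.4,Relatively bad
mean,summer,29.5,Bad
mean,fall,30.2,Relatively bad
mean,winter,31.4,Relatively bad
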