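station,season,score,label
1,spring,49.32,Bad
1,summer,43.05,Bad
1,fall,29.4,Bad
1,winter,44.38,Bad
1,mean,41.5,Bad
2,spring,44.21,Bad
2,summer,39.13,Bad
2,fall,39.54,Bad
2,winter,46.52,Bad
2,mean,42.3,Bad
3,spring,47.22,Bad
3,summer,40.72,Bad
3,fall,43.51,Bad
3,winter,45.67,Bad
3,mean,44.2,Bad
4,spring,33.82,Bad
4,summer,32.61,Bad
4,fall,33.9,Bad
4,winter,33.41,Bad
4,mean,33.4,Bad
5,spring,42.93,Bad
5,summer,38.79,Bad
5,fall,36.46,Bad
5,winter,42.6,Bad
5,mean,40.2,Bad
mean,spring,43.5,Bad
mean,summer,38.9,Bad
mean,fall,36.6,Bad
mean,winter,42.5,Bad
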