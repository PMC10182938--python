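group,metric,stat,value
children,cdi,min,0.21
children,cdi,mean,0.39
children,cdi,max,1
children,cdi,sd,0.11
children,hq,min,0.35
children,hq,mean,0.63
children,hq,max,1.60
children,hq,sd,0.19
teenagers,cdi,min,0.11
teenagers,cdi,mean,0.2
teenagers,cdi,max,0.51
teenagers,cdi,sd,0.06
teenagers,hq,min,0.18
teenagers,hq,mean,0.32
teenagers,hq,max,0.83
teenagers,hq,sd,0.10
adults,cdi,min,0.06
adults,cdi,mean,0.13
adults,cdi,max,0.33
adults,cdi,sd,0.03
adults,hq,min,0.11
adults,hq,mean,0.21
adults,hq,max,0.53
adults,hq,sd,0.06
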