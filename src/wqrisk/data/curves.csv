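parameter,x,q
fecal_coliform,0,98
fecal_coliform,1,97
fecal_coliform,10,72
fecal_coliform,100,43
fecal_coliform,1000,22
fecal_coliform,10000,9
fecal_coliform,100000,2
bod5,0,96
bod5,2,80
bod5,4,63
bod5,6,52
bod5,8,43
bod5,10,37
bod5,15,24
bod5,20,17
bod5,25,12
bod5,30,2
no3,0,97
no3,5,75
no3,10,53
no3,15,43
no3,20,37
no3,30,28
no3,40,23
no3,50,19
no3,100,5
do_sat,0,2
do_sat,10,8
do_sat,20,13
do_sat,30,20
do_sat,40,30
do_sat,50,43
do_sat,60,56
do_sat,70,77
do_sat,80,88
do_sat,90,95
do_sat,100,99
do_sat,110,95
do_sat,120,90
do_sat,130,85
do_sat,140,78
ph,2,2
ph,3,4
ph,4,8
ph,5,24
ph,6,55
ph,7,90
ph,7.5,93
ph,8,82
ph,9,47
ph,10,19
ph,11,7
ph,12,2
temperature,0,78
temperature,5,85
temperature,10,90
temperature,15,80
temperature,20,65
temperature,25,50
temperature,30,38
temperature,35,28
temperature,40,20
turbidity,0,97
turbidity,5,84
turbidity,10,76
turbidity,20,60
turbidity,30,52
turbidity,40,45
turbidity,50,39
turbidity,60,34
turbidity,80,26
turbidity,100,17
ts,0,80
ts,50,86
ts,100,80
ts,150,72
ts,200,62
ts,300,48
ts,400,35
ts,500,20
po4,0,99
po4,0.5,58
po4,1,40
po4,2,28
po4,3,22
po4,4,18
po4,6,14
po4,10,8
ec,0,100
ec,250,85
ec,500,70
ec,750,60
ec,1000,50
ec,1500,35
ec,2000,25
ec,3000,12
ec,5000,5
ec,10000,1
cod,0,100
cod,10,75
cod,20,58
cod,30,45
cod,40,34
cod,54,25
cod,80,15
cod,100,10
cod,200,1
nh4,0,100
nh4,0.2,85
nh4,0.5,72
nh4,1,55
nh4,2,35
nh4,5,15
nh4,10,1
th,0,100
th,50,92
th,100,80
th,200,62
th,300,48
th,400,35
th,500,26
th,1000,8
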