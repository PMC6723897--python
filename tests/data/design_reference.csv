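setting_id,dr_nominal,hpmc_nominal,force,role,origin
1,6,10,63.8,test,factorial
2,8,10,63.8,train,factorial
3,10,10,63.8,train,factorial
4,6,20,63.8,test,factorial
5,8,20,63.8,train,factorial
6,10,20,63.8,train,factorial
7,6,30,63.8,train,factorial
8,8,30,63.8,train,factorial
9,10,30,63.8,train,factorial
10,6,10,95.7,train,factorial
11,8,10,95.7,train,factorial
12,10,10,95.7,train,factorial
13,6,20,95.7,train,factorial
14,8,20,95.7,test,factorial
15,10,20,95.7,train,factorial
16,6,30,95.7,train,factorial
17,8,30,95.7,test,factorial
18,10,30,95.7,train,factorial
19,6,10,127.6,train,factorial
20,8,10,127.6,train,factorial
21,10,10,127.6,train,factorial
22,6,20,127.6,train,factorial
23,8,20,127.6,train,factorial
24,10,20,127.6,train,factorial
25,6,30,127.6,train,factorial
26,8,30,127.6,train,factorial
27,10,30,127.6,test,factorial
28,7,20,63.8,train,additional
29,7.5,20,63.8,test,additional
30,8.5,20,63.8,train,additional
31,9,20,63.8,train,additional
32,8,5,63.8,train,additional
33,8,15,63.8,train,additional
34,8,25,63.8,test,additional
35,8,35,63.8,train,additional
36,8,20,31.9,train,additional
37,8,20,159.5,train,additional
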