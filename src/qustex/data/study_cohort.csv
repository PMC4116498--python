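patient,age,menopausal_status,tumor_size_cm,histology,grade,er_pr,her2,response
1,55,unknown,5.4,ductal,,neg,pos,Good
2,53,unknown,7.4,ductal,2,pos,neg,Good
3,41,pre,4.0,ductal,3,pos,pos,Poor
4,50,pre,5.0,ductal,,neg,pos,Good
5,33,pre,3.0,ductal,1,pos,neg,Good
6,33,pre,8.0,ductal,,pos,pos,Good
7,48,post,8.1,ductal,2,pos,neg,Good
8,36,pre,5.8,ductal,2,pos,neg,Poor
9,40,pre,4.4,ductal,3,neg,neg,Good
10,38,pre,9.2,ductal,2,pos,neg,Poor
11,53,unknown,12.7,metaplastic,3,neg,neg,Poor
12,50,pre,13.0,ductal,3,neg,neg,Good
13,49,pre,8.9,ductal,3,neg,pos,Good
14,40,pre,3.0,ductal,3,pos,pos,Good
15,47,pre,5.2,ductal,2,pos,neg,Good
16,38,pre,9.0,ductal,2,pos,neg,Good
17,38,pre,8.0,ductal,,neg,pos,Good
18,47,pre,10.0,ductal,2,pos,neg,Poor
19,57,post,7.9,ductal,,neg,neg,Good
20,47,pre,7.4,ductal,,neg,pos,Good
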