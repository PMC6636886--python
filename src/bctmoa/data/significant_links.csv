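bct_code,moa_id,frequency,p_display
4.1,1,17,.013
4.1,2,20,.024
1.1,14,15,.003
1.2,4,65,.008
1.2,11,9,.026
1.2,2,18,.038
3.1,12,34,<.001
3.1,3,5,.037
6.1,4,60,.003
6.1,2,17,.020
6.1,23,3,.044
1.4,14,14,.001
2.2,16,19,<.001
2.2,1,13,.013
5.1,1,18,<.001
5.1,6,26,<.001
5.1,17,19,<.001
5.1,26,10,<.001
5.1,8,28,.004
8.1,2,24,<.001
8.1,4,47,.013
6.2,16,31,<.001
6.2,12,9,.043
5.3,6,20,<.001
5.3,17,16,<.001
5.3,1,13,.002
2.3,14,18,<.001
9.1,25,2,.007
9.1,3,4,.023
12.5,11,8,<.001
7.1,10,8,<.001
7.1,24,6,.002
7.1,11,5,.036
8.7,4,28,<.001
9.2,6,12,<.001
9.2,17,9,<.001
9.2,22,3,.005
9.2,18,5,.023
13.2,19,2,<.050
13.2,17,7,.014
8.2,14,5,.016
10.4,7,3,.020
15.3,4,23,<.001
12.1,11,9,<.001
12.1,24,3,.020
1.8,9,4,.002
6.3,16,13,<.001
6.3,8,12,.043
15.1,4,27,<.001
2.7,16,5,.020
2.7,22,2,.027
11.2,4,12,.039
5.2,17,4,.025
1.9,21,1,.039
2.4,14,5,.024
5.6,6,6,.005
5.6,17,5,.006
5.6,13,2,.024
1.3,9,4,.003
3.2,12,4,.023
3.2,11,3,.026
1.6,9,3,.001
1.6,14,3,.019
12.3,20,1,.027
13.1,19,2,.011
12.2,11,3,.004
12.2,12,6,<.001
10.3,7,2,.005
8.3,24,3,.001
8.3,14,3,.024
1.7,9,2,.012
15.2,18,3,.008
15.2,21,1,.026
10.1,17,1,.048
2.1,20,1,.019
2.1,12,2,.036
8.6,2,2,.047
9.3,6,3,.017
13.5,21,1,.016
13.5,18,2,.028
5.5,13,2,.002
8.4,14,4,.006
8.4,24,2,.023
8.4,10,2,.036
7.8,7,1,.038
10.7,18,1,.036
13.3,17,1,.048
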