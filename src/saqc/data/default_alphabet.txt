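# saqc structural-alphabet parameters
version = saqc-default-1.0

[letters]
A a V W L M N T X B C D E F G H I J K O P Q R S U Y Z

[emission]
# letter  mean(d1 d2 d3 h)  covariance upper triangle (row-major)
A 5.466076 5.227366 5.466076 2.976050 0.002500 0.000000 0.000000 0.000000 0.002500 0.000000 0.000000 0.002500 0.000000 0.002500
a 5.480909 5.221932 5.475256 -2.926530 0.015681 0.003977 -0.004574 0.006169 0.018225 0.004216 -0.007278 0.013582 0.003861 0.023654
V 5.403586 5.518287 5.397607 -3.348582 0.015471 -0.000139 -0.003403 0.006744 0.028480 0.000001 -0.017078 0.016411 0.007570 0.024463
W 5.556591 5.013933 5.571669 -2.348445 0.016217 0.005494 -0.004942 0.009351 0.023096 0.005733 -0.011595 0.015107 0.008213 0.065660
L 6.899872 10.478753 6.910599 -0.132118 0.003612 0.000932 0.000246 0.000381 0.003669 0.000824 0.000087 0.003545 -0.000394 0.006109
M 6.916752 10.482882 6.903266 0.199724 0.006507 0.003758 0.001731 0.000965 0.007747 0.004188 -0.000053 0.007081 -0.000760 0.012183
N 6.939945 10.455591 6.861247 0.573599 0.006470 0.003760 0.001974 0.001773 0.007919 0.004421 0.000139 0.007076 -0.000189 0.017427
T 6.820987 10.429330 6.961762 -0.660773 0.007094 0.004661 0.001488 0.003819 0.008722 0.003738 0.005774 0.007537 -0.003042 0.053171
X 6.983545 10.410827 6.817692 1.083533 0.005790 0.002447 0.001300 0.004342 0.007689 0.004424 -0.004484 0.007110 -0.002952 0.046024
B 5.617467 5.304819 6.090505 0.187350 0.126916 0.140694 -0.022857 -0.017996 0.243019 0.023464 0.005015 0.038263 0.006133 0.565507
C 5.481421 5.347516 5.590933 2.820413 0.067238 0.042320 -0.015385 -0.017907 0.116592 0.028205 0.014780 0.080830 -0.075895 0.186782
D 5.470766 5.361063 5.623308 -2.748606 0.074252 0.031292 -0.016655 0.031076 0.144985 0.030527 -0.065415 0.100313 0.101853 0.302721
E 5.672489 6.790906 6.827256 1.026375 0.142330 0.072122 -0.068830 0.000679 0.273739 0.089288 -0.035132 0.110847 -0.063356 0.315487
F 5.662276 6.791078 6.832664 -1.033751 0.152300 0.097812 -0.060685 0.010575 0.346616 0.110884 0.048696 0.114536 0.058943 0.319489
G 5.646306 6.903046 5.633851 -3.485927 0.213687 -0.013239 -0.013193 0.008237 0.207734 0.028978 0.010939 0.184899 0.032516 0.095221
H 5.640380 6.962548 5.640910 3.477093 0.209109 -0.008732 -0.008413 -0.005807 0.215119 0.020669 -0.012211 0.185705 -0.033955 0.103227
I 6.393963 8.053037 5.564885 -3.363119 0.201211 0.004829 -0.032961 -0.059404 0.139693 0.045086 0.032965 0.202984 -0.052890 0.146599
J 5.601546 8.076721 6.605221 2.710494 0.161684 0.056643 0.028512 0.003190 0.266825 -0.021967 -0.041571 0.173109 -0.067356 0.226246
K 5.597601 8.103594 6.499128 -2.737451 0.151350 0.048248 0.029773 -0.020827 0.245261 -0.029531 0.035453 0.229651 0.030171 0.197471
O 6.439629 8.156808 5.568285 3.316445 0.200447 0.019820 -0.037438 0.045049 0.155481 0.039648 -0.045197 0.184151 0.052405 0.145838
P 5.937305 8.793432 5.539324 1.149038 0.275914 0.130041 -0.025105 0.030482 0.155506 0.102775 -0.039527 0.183869 -0.022365 0.284909
Q 5.954827 8.890772 5.627121 -0.752422 0.305454 0.153349 -0.025751 0.006433 0.186122 0.123769 0.057240 0.242370 0.050101 0.307974
R 6.673087 9.058345 5.883804 -2.654735 0.140562 0.048343 -0.004332 -0.032995 0.093240 0.074432 -0.019678 0.194214 -0.121940 0.209375
S 6.631791 9.242527 6.137516 2.582479 0.157051 0.045723 -0.041947 0.039062 0.117478 0.083472 -0.020677 0.214364 0.042398 0.193676
U 6.533948 9.696771 6.555979 -1.777882 0.179494 0.112081 -0.036261 -0.011903 0.145072 0.042132 0.006481 0.180129 -0.056737 0.211404
Y 6.642020 9.899583 6.582210 1.233056 0.170087 0.108202 -0.031338 -0.012004 0.169229 0.079590 0.013702 0.192091 0.083259 0.262328
Z 6.858270 10.393769 6.856268 -0.118201 0.040713 0.026793 0.000555 0.008175 0.054666 0.041166 0.008589 0.054808 -0.001120 0.126947

[ss_class]
A helix
a helix
V helix
W helix
L strand
M strand
N strand
T strand
X strand
B other
C other
D other
E other
F other
G other
H other
I other
J other
K other
O other
P other
Q other
R other
S other
U other
Y other
Z other
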