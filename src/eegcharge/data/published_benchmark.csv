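band,classifier,corr_tgt,inc_tgt,corr_std,inc_std,acc,recall,prec
broadband,Logistic regression,55,32,39,16,0.662,0.549,0.709
broadband,Decision jungle,42,31,40,29,0.577,0.563,0.580
broadband,Support vector machine,35,25,46,36,0.561,0.521,0.698
broadband,Avg. perceptron classifier,53,32,39,18,0.684,0.549,0.684
broadband,Bayes point machine,33,15,56,38,0.627,0.789,0.596
broadband,Neural network,55,41,30,16,0.652,0.423,0.652
broadband,Locally-deep support vector,55,34,37,16,0.698,0.648,0.561
alpha,Logistic regression,54,27,44,17,0.690,0.620,0.721
alpha,Decision jungle,48,27,44,23,0.648,0.620,0.657
alpha,Support vector machine,41,29,42,30,0.585,0.577,0.683
alpha,Avg. perceptron classifier,51,28,43,20,0.662,0.606,0.683
alpha,Bayes point machine,46,28,43,25,0.627,0.606,0.632
alpha,Neural network,61,37,34,10,0.669,0.479,0.773
alpha,Locally-deep support vector,41,29,42,30,0.585,0.592,0.583
beta,Logistic regression,51,23,48,20,0.697,0.676,0.706
beta,Decision jungle,51,24,47,20,0.690,0.662,0.701
beta,Support vector machine,53,26,45,18,0.690,0.634,0.714
beta,Avg. perceptron classifier,49,24,47,22,0.676,0.662,0.681
beta,Bayes point machine,35,13,58,36,0.655,0.817,0.617
beta,Neural network,58,36,35,13,0.655,0.493,0.729
beta,Locally-deep support vector,46,29,42,25,0.620,0.592,0.627
gamma,Logistic regression,52,33,38,19,0.634,0.535,0.667
gamma,Decision jungle,42,30,41,29,0.585,0.577,0.586
gamma,Support vector machine,52,29,42,19,0.662,0.592,0.689
gamma,Avg. perceptron classifier,49,32,39,22,0.620,0.549,0.639
gamma,Bayes point machine,34,17,54,37,0.620,0.761,0.593
gamma,Neural network,50,33,38,21,0.620,0.535,0.644
gamma,Locally-deep support vector,41,31,40,30,0.570,0.563,0.571
delta,Logistic regression,56,28,43,15,0.697,0.606,0.741
delta,Decision jungle,49,23,48,22,0.683,0.775,0.743
delta,Support vector machine,56,27,44,15,0.704,0.620,0.746
delta,Avg. perceptron classifier,56,27,44,15,0.704,0.620,0.746
delta,Bayes point machine,39,14,57,32,0.676,0.803,0.640
delta,Neural network,62,37,34,9,0.676,0.479,0.791
delta,Locally-deep support vector,50,28,43,21,0.655,0.606,0.672
theta,Logistic regression,53,24,47,18,0.704,0.662,0.723
theta,Decision jungle,51,31,40,20,0.641,0.563,0.667
theta,Support vector machine,50,26,45,21,0.669,0.521,0.569
theta,Avg. perceptron classifier,45,27,44,26,0.627,0.620,0.629
theta,Bayes point machine,29,14,57,42,0.606,0.803,0.576
theta,Neural network,61,41,30,10,0.641,0.423,0.750
theta,Locally-deep support vector,50,26,45,21,0.669,0.521,0.569
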