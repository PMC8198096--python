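cluster,TN,Th,TC,Tr,DN,D,M,C,N,mu1,mu2,H,Igamma,Gbeta
1,3.66e-2,4.90e-2,9.67e-2,2.70e-2,6.41e-2,1.23e-5,2.64e-2,4.64e-2,1.55e-2,4.97e-1,5.12e-1,1.47,3.89,2.55e-1
2,2.63e-2,2.81e-2,3.25e-2,1.09e-2,4.37e-2,5.95e-2,2.76e-2,2.38e-2,1.46e-3,7.58e-1,1.79e-1,6.04e-1,9.38e-1,5.57e-1
3,1.38e-1,2.20e-1,8.59e-2,6.26e-2,1.53e-1,2.61e-1,1.56e-1,1.83e-1,0,7.51e-1,7.14e-1,1.03,4.90e-1,3.87
4,1.58e-1,1.71e-2,6.35e-2,9.72e-2,6.20e-1,4.68e-1,1.01e-1,1.22e-1,0,4.14e-1,5.77e1,1.46e1,0,2.56e1
5,1.36e-2,5.24e-2,3.27e-2,3.78e-2,4.72e-5,9.11e-3,1.55e-2,2.69e-2,7.03e-3,4.59e-1,2.30,1.18,4.08e-1,3.46e-1
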