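time,survival,at_risk
1.0509772827308503,0.9090909090909091,11
1.2352098616804859,0.8181818181818181,10
4.590260216587546,0.7272727272727272,9
5.089090469508245,0.6363636363636362,8
5.256297280643519,0.5454545454545454,7
14.23632242012849,0.43636363636363634,5
17.30575414856406,0.32727272727272727,4
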