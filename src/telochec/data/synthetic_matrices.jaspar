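>MA0359.1 RAP1
A [ 97  1 97  1  1  1 97  1 97  1 97  1  1 ]
C [  1 97  1 97 97 97  1  1  1 97  1 97 97 ]
G [  1  1  1  1  1  1  1  1  1  1  1  1  1 ]
T [  1  1  1  1  1  1  1 97  1  1  1  1  1 ]
>MA0403.1 TBF1
A [  1  1 97  1  1  1  1  1 97  1  1  1  1 ]
C [  1  1  1  1  1  1  1  1  1  1  1  1  1 ]
G [  1  1  1 97 97 97  1  1  1 97 97 97  1 ]
T [ 97 97  1  1  1  1 97 97  1  1  1  1 97 ]
>MA0363.1 REB1
A [  1  1 97  1  1  1  1  1 ]
C [  1  1  1 97 97 97  1  1 ]
G [  1  1  1  1  1  1 97 97 ]
T [ 97 97  1  1  1  1  1  1 ]
>MA0265.1 ABF1
A [ 49  1  1 49  1 25 25 25 25 25 97  1  1 97 ]
C [  1  1 97  1 49 25 25 25 25 25  1 97  1  1 ]
G [ 49  1  1 49  1 25 25 25 25 25  1  1 97  1 ]
T [  1 97  1  1 49 25 25 25 25 25  1  1  1  1 ]
>ACS ORC_ACS
A [  1  1  1  1 97  1 49  1  1  1 49  1  1  1  1  1  1 ]
C [  1  1  1  1  1  1  1  1  1  1  1  1  1 49  1  1  1 ]
G [  1  1  1  1  1  1 49  1  1  1  1  1 97  1  1  1  1 ]
T [ 97 97 97 97  1 97  1 97 97 97 49 97  1 49 97 97 97 ]
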