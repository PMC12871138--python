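P00001
P00002
P00003
P00004
P00005
P00006
P00007
P00008
P00009
P00010
P00011
P00012
P00013
P00014
P00015
P00016
P00017
P00018
P00019
P00020
P00021
P00022
P00023
P00024
P00025
P00026
P00027
P00028
P00029
P00030
P00031
P00032
P00033
P00034
P00035
P00036
P00037
P00038
P00039
P00040
P00041
P00042
P00043
P00044
P00045
P00046
P00047
P00048
P00049
P00050
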