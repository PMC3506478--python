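freq
A	0.076747923252076758
R	0.051690948309051694
N	0.042644957355042652
D	0.051543948456051550
C	0.019802980197019805
Q	0.040751959248040752
E	0.061829938170061841
G	0.073151926848073159
H	0.022943977056022944
I	0.053760946239053767
L	0.091903908096091905
K	0.058675941324058678
M	0.023825976174023829
F	0.040125959874040135
P	0.050900949099050907
S	0.068764931235068771
T	0.058564941435058568
W	0.014260985739014262
Y	0.032101967898032102
V	0.066004933995066004
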