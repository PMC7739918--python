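name,length_mm,r_prox_mm,r_dist_mm,E_MPa
ascending aorta,40,12,12,0.4
aortic arch I,20,11.2,11.2,0.4
brachiocephalic,34,6.2,6.2,0.4
aortic arch II,39,11,11,0.4
L. common carotid,208,2.5,2.5,0.4
R. common carotid,177,2.5,2.5,0.4
R. subclavian,34,4.23,4.23,0.4
thoracic aorta,156,9.99,9.99,0.4
L. subclavian,34,4.23,4.23,0.4
L ext. carotid,177,1.5,1.5,0.8
L int. carotid I,177,2,2,0.8
R int. carotid I,177,2,2,0.8
R ext. carotid,177,1.5,1.5,0.8
R. vertebral,148,1.36,1.36,0.8
R. brachial,422,4.03,4.03,0.4
L. brachial,422,4.03,4.03,0.4
L. vertebral,148,1.36,1.36,0.8
L. PCoA,15,0.73,0.73,1.6
R. PCoA,15,0.73,0.73,1.6
basilar I,5.6,1.62,1.62,1.6
L. MCA,119,1.43,1.43,1.6
R. MCA,119,1.43,1.43,1.6
"L. ACA, A1",12,1.17,1.17,1.6
"R. ACA, A1",12,1.17,1.17,1.6
"L. PCA, P1",5,1.07,1.07,1.6
"R. PCA, P1",5,1.07,1.07,1.6
"L. ACA, A2",103,1.2,1.2,1.6
"R. ACA, A2",103,1.2,1.2,1.6
ACoA,3,0.74,0.74,1.6
"L. PCA, P2",86,1.05,1.05,1.6
"R. PCA, P2",86,1.05,1.05,1.6
R. SCA,10,0.78,0.78,1.6
L. SCA,10,0.78,0.78,1.6
R. AICA,10,0.63,0.63,1.6
L. AICA,10,0.63,0.63,1.6
basilar II,5.6,1.62,1.62,1.6
pontine I,5,0.2,0.2,1.6
pontine II,5,0.2,0.2,1.6
pontine III,5,0.2,0.2,1.6
pontine IV,5,0.2,0.2,1.6
pontine V,5,0.2,0.2,1.6
pontine VI,5,0.2,0.2,1.6
pontine VII,5,0.2,0.2,1.6
pontine VIII,5,0.2,0.2,1.6
pontine IX,5,0.2,0.2,1.6
pontine X,5,0.2,0.2,1.6
pontine XI,5,0.2,0.2,1.6
pontine XII,5,0.2,0.2,1.6
basilar III,5.6,1.62,1.62,1.6
basilar IV,5.6,1.62,1.62,1.6
basilar V,5.6,1.62,1.62,1.6
R. PICA,10,0.63,0.63,1.6
L. PICA,10,0.63,0.63,1.6
R. vertebral II,20,1.36,1.36,0.8
L. vertebral II,20,1.36,1.36,0.8
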