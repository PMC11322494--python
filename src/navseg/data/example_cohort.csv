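id,sex,age_years,tumor_type,tumor_location,surgical_position,preop_volume_cm3,residual_on_imri,residual_on_ius2,evaluable_ius,evaluable_quantitative
1,Male,12,Pilocytic astrocytoma,Hemispheric,Supine,59.4,n,n,true,true
2,Female,4,Ependymoma,Hemispheric,Supine,63.3,n,n,true,true
3,Male,8,Low grade glioma,Hemispheric,Supine,24.4,n,n,true,true
4,Female,6,Pilocytic astrocytoma,Hemispheric,Supine,32.4,y,y,true,true
5,Male,18,Low grade glioma,Hemispheric,Supine,0.884,n,y,true,true
6,Male,10,DNET,Hemispheric,Supine,7.76,y,y,true,true
7,Female,2,High grade glioma,Hemispheric,Supine,77.0,y,y,true,false
8,Male,5,DNET,Hemispheric,Supine,18.3,n,n,true,true
9,Female,3,Ganglioglioma,Infratentorial,Prone,38.6,y,y,true,true
10,Female,9,Medulloblastoma,Infratentorial,Prone,21.3,y,y,true,true
11,Male,10,Pilocytic astrocytoma,Infratentorial,Prone,6.17,y,y,true,true
12,Female,3,Medulloblastoma,Infratentorial,Prone,21.1,y,y,true,true
13,Male,9,Pilocytic astrocytoma,Infratentorial,Prone,3.68,n,n,true,true
14,Male,2,Ependymoma,Infratentorial,Prone,107,n,,false,false
15,Male,13,Medulloblastoma,Infratentorial,Prone,0.347,n,n,true,true
16,Female,3,Pilocytic astrocytoma,Infratentorial,Prone,42.9,y,y,true,true
17,Male,7,Pilocytic astrocytoma,Infratentorial,Prone,25.3,n,n,true,true
18,Male,4,Pilocytic astrocytoma,Infratentorial,Prone,17.7,n,n,true,true
19,Male,9,Pilocytic astrocytoma,Intraventricular,Supine,3.30,y,y,true,true
20,Male,13,Giant cell astrocytoma,Intraventricular,Supine,1.10,n,y,true,true
21,Male,9,Pilocytic astrocytoma,Suprasellar,Supine,20.3,y,y,true,true
22,Female,7,Craniopharyngioma,Suprasellar,Supine,37.4,n,n,true,true
23,Male,9,Craniopharyngioma,Suprasellar,Supine,0.531,n,n,true,true
24,Male,7,Craniopharyngioma,Suprasellar,Supine,16.7,n,n,true,true
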