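drug,code,source
bortezomib,356733,reference
carfilzomib,1302966,reference
ixazomib,1723735,reference
lenalidomide,342369,reference
pomalidomide,1369713,reference
oprozomib,900001,synthetic
gefitinib,900002,synthetic
erlotinib,900003,synthetic
vandetanib,900004,synthetic
afatinib,900005,synthetic
dacomitinib,900006,synthetic
poziotinib,900007,synthetic
tesevatinib,900008,synthetic
osimertinib,900009,synthetic
lazertinib,900010,synthetic
rociletinib,900011,synthetic
tarloxotinib,900012,synthetic
bicalutamide,900013,synthetic
nilutamide,900014,synthetic
flutamide,900015,synthetic
abiraterone,900016,synthetic
enzalutamide,900017,synthetic
darolutamide,900018,synthetic
apalutamide,900019,synthetic
leuprolide,900020,synthetic
goserelin,900021,synthetic
degarelix,900022,synthetic
finasteride,900023,synthetic
dutasteride,900024,synthetic
megestrol acetate,900025,synthetic
rifabutin,900026,synthetic
clarithromycin,900027,synthetic
azithromycin,900028,synthetic
imipenem,900029,synthetic
propafenone,900030,synthetic
procainamide,900031,synthetic
warfarin,900032,synthetic
pembrolizumab,900033,synthetic
nivolumab,900034,synthetic
cisplatin,900035,synthetic
carboplatin,900036,synthetic
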