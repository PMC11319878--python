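class,drug
proteasome inhibitor,bortezomib
proteasome inhibitor,carfilzomib
proteasome inhibitor,ixazomib
proteasome inhibitor,oprozomib
first-generation EGFR inhibitor,gefitinib
first-generation EGFR inhibitor,erlotinib
first-generation EGFR inhibitor,vandetanib
second-generation EGFR inhibitor,afatinib
second-generation EGFR inhibitor,dacomitinib
second-generation EGFR inhibitor,poziotinib
second-generation EGFR inhibitor,tesevatinib
third-generation EGFR inhibitor,osimertinib
third-generation EGFR inhibitor,lazertinib
third-generation EGFR inhibitor,rociletinib
third-generation EGFR inhibitor,tarloxotinib
first-generation antiandrogen,bicalutamide
first-generation antiandrogen,nilutamide
first-generation antiandrogen,flutamide
second-generation antiandrogen,abiraterone
second-generation antiandrogen,enzalutamide
second-generation antiandrogen,darolutamide
second-generation antiandrogen,apalutamide
androgen deprivation therapy,leuprolide
androgen deprivation therapy,goserelin
androgen deprivation therapy,degarelix
5-alpha reducing agent,finasteride
5-alpha reducing agent,dutasteride
5-alpha reducing agent,megestrol acetate
LHRH agonist,goserelin
LHRH agonist,leuprolide
immunomodulatory agent,lenalidomide
immunomodulatory agent,pomalidomide
antibiotics,rifabutin
antibiotics,clarithromycin
antibiotics,azithromycin
antibiotics,imipenem
antiarrhythmic agents,propafenone
antiarrhythmic agents,procainamide
anticoagulants,warfarin
PD-1 antibody,pembrolizumab
PD-1 antibody,nivolumab
platinum chemotherapy,cisplatin
platinum chemotherapy,carboplatin
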