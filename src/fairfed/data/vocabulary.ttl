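# fairfed consortium mini-vocabulary.
#
# A small curated terminology in the style of the National Cancer Institute
# Thesaurus (NCIt, OBO PURL form) and the Radiation Oncology Ontology (ROO,
# P-coded predicates), covering the variables a head-and-neck-cancer
# consortium needs for case-mix exploration and survival modelling.
# NCIt codes are the published ones where confidently known; codes in the
# C91xxxxx block are synthetic placeholders minted for this vocabulary.
#
# ff:order fixes the canonical display order of variables and of the
# categories within a variable; rdfs:subClassOf carries the value-term
# hierarchy (e.g. T4a/T4b under T4) used by the materialized closure.

@prefix ncit: <http://purl.obolibrary.org/obo/NCIT_> .
@prefix roo:  <http://www.cancerdata.org/roo/> .
@prefix ff:   <https://w3id.org/fairfed/vocab#> .
@prefix owl:  <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd:  <http://www.w3.org/2001/XMLSchema#> .

### Root classes ############################################################

ncit:C16960 a owl:Class ; rdfs:label "Patient" .

### Units ###################################################################

ncit:C25301 a owl:Class ; rdfs:label "Day" ; ff:isUnit true .
ncit:C29848 a owl:Class ; rdfs:label "Year" ; ff:isUnit true .
ncit:C28252 a owl:Class ; rdfs:label "Millimeter Cubed" ; ff:isUnit true .

### Variables (ROO-style predicates) ########################################

roo:P100018 a owl:ObjectProperty ;
    rdfs:label "Sex" ;
    ff:kind "categorical" ;
    ff:order 3 .

roo:P100016 a owl:DatatypeProperty ;
    rdfs:label "Age in years" ;
    ff:kind "continuous" ;
    ff:unit ncit:C29848 ;
    ff:order 2 .

roo:P100242 a owl:ObjectProperty ;
    rdfs:label "Tumour stage" ;
    ff:kind "categorical" ;
    ff:order 4 .

roo:P100243 a owl:ObjectProperty ;
    rdfs:label "Nodal stage" ;
    ff:kind "categorical" ;
    ff:order 5 .

roo:P100244 a owl:ObjectProperty ;
    rdfs:label "Metastasis stage" ;
    ff:kind "categorical" ;
    ff:order 6 .

roo:P100245 a owl:ObjectProperty ;
    rdfs:label "Overall stage (7th ed.)" ;
    ff:kind "categorical" ;
    ff:order 7 .

roo:P100202 a owl:ObjectProperty ;
    rdfs:label "Tumour location" ;
    ff:kind "categorical" ;
    ff:order 8 .

roo:P100246 a owl:ObjectProperty ;
    rdfs:label "HPV status" ;
    ff:kind "categorical" ;
    ff:order 9 .

roo:P100231 a owl:ObjectProperty ;
    rdfs:label "Radiotherapy type" ;
    ff:kind "categorical" ;
    ff:order 10 .

roo:P100028 a owl:ObjectProperty ;
    rdfs:label "Survival status" ;
    ff:kind "categorical" ;
    ff:order 11 .

roo:P100247 a owl:DatatypeProperty ;
    rdfs:label "Survival days" ;
    ff:kind "continuous" ;
    ff:unit ncit:C25301 ;
    ff:order 12 .

# Hand-picked radiomics features of the primary gross tumour volume (GTV).
roo:P200001 a owl:DatatypeProperty ; rdfs:label "GTV volume" ;
    ff:kind "continuous" ; ff:unit ncit:C28252 ; ff:order 13 .
roo:P200002 a owl:DatatypeProperty ; rdfs:label "GTV surface area" ;
    ff:kind "continuous" ; ff:order 14 .
roo:P200003 a owl:DatatypeProperty ; rdfs:label "GTV sphericity" ;
    ff:kind "continuous" ; ff:order 15 .
roo:P200004 a owl:DatatypeProperty ; rdfs:label "GTV intensity mean" ;
    ff:kind "continuous" ; ff:order 16 .
roo:P200005 a owl:DatatypeProperty ; rdfs:label "GTV texture entropy" ;
    ff:kind "continuous" ; ff:order 17 .

### Value terms #############################################################

# Sex
ncit:C16576 a owl:Class ; rdfs:label "Female" ; ff:categoryOf roo:P100018 ; ff:order 1 .
ncit:C20197 a owl:Class ; rdfs:label "Male"   ; ff:categoryOf roo:P100018 ; ff:order 2 .

# T stage (AJCC 7th); T4a and T4b are subclasses of T4, not top-level
# categories: a query for T4 also returns T4a- and T4b-coded subjects.
ncit:C48720 a owl:Class ; rdfs:label "T1" ; ff:categoryOf roo:P100242 ; ff:order 1 .
ncit:C48724 a owl:Class ; rdfs:label "T2" ; ff:categoryOf roo:P100242 ; ff:order 2 .
ncit:C48728 a owl:Class ; rdfs:label "T3" ; ff:categoryOf roo:P100242 ; ff:order 3 .
ncit:C48732 a owl:Class ; rdfs:label "T4" ; ff:categoryOf roo:P100242 ; ff:order 4 .
ncit:C48733 a owl:Class ; rdfs:label "T4a" ; rdfs:subClassOf ncit:C48732 .
ncit:C48734 a owl:Class ; rdfs:label "T4b" ; rdfs:subClassOf ncit:C48732 .
ncit:C48719 a owl:Class ; rdfs:label "Tx" ; ff:categoryOf roo:P100242 ; ff:order 5 .

# N stage
ncit:C48705 a owl:Class ; rdfs:label "N0" ; ff:categoryOf roo:P100243 ; ff:order 1 .
ncit:C48706 a owl:Class ; rdfs:label "N1" ; ff:categoryOf roo:P100243 ; ff:order 2 .
ncit:C48786 a owl:Class ; rdfs:label "N2" ; ff:categoryOf roo:P100243 ; ff:order 3 .
ncit:C48714 a owl:Class ; rdfs:label "N3" ; ff:categoryOf roo:P100243 ; ff:order 4 .
ncit:C48718 a owl:Class ; rdfs:label "Nx" ; ff:categoryOf roo:P100243 ; ff:order 5 .

# M stage
ncit:C48699 a owl:Class ; rdfs:label "M0" ; ff:categoryOf roo:P100244 ; ff:order 1 .
ncit:C48700 a owl:Class ; rdfs:label "M1" ; ff:categoryOf roo:P100244 ; ff:order 2 .
ncit:C48704 a owl:Class ; rdfs:label "Mx" ; ff:categoryOf roo:P100244 ; ff:order 3 .

# Overall stage (AJCC 7th)
ncit:C27966 a owl:Class ; rdfs:label "I"   ; ff:categoryOf roo:P100245 ; ff:order 1 .
ncit:C28054 a owl:Class ; rdfs:label "II"  ; ff:categoryOf roo:P100245 ; ff:order 2 .
ncit:C27970 a owl:Class ; rdfs:label "III" ; ff:categoryOf roo:P100245 ; ff:order 3 .
ncit:C27971 a owl:Class ; rdfs:label "IV"  ; ff:categoryOf roo:P100245 ; ff:order 4 .
ncit:C9100005 a owl:Class ; rdfs:label "Unspecified" ; ff:categoryOf roo:P100245 ; ff:order 5 .

# Tumour location
ncit:C12423 a owl:Class ; rdfs:label "Nasopharynx" ; ff:categoryOf roo:P100202 ; ff:order 1 .
ncit:C12762 a owl:Class ; rdfs:label "Oropharynx"  ; ff:categoryOf roo:P100202 ; ff:order 2 .
ncit:C12246 a owl:Class ; rdfs:label "Hypopharynx" ; ff:categoryOf roo:P100202 ; ff:order 3 .
ncit:C12420 a owl:Class ; rdfs:label "Larynx"      ; ff:categoryOf roo:P100202 ; ff:order 4 .
ncit:C9100006 a owl:Class ; rdfs:label "Unknown"   ; ff:categoryOf roo:P100202 ; ff:order 5 .

# HPV status
ncit:C9100001 a owl:Class ; rdfs:label "Positive" ; ff:categoryOf roo:P100246 ; ff:order 1 .
ncit:C9100002 a owl:Class ; rdfs:label "Negative" ; ff:categoryOf roo:P100246 ; ff:order 2 .
ncit:C9100003 a owl:Class ; rdfs:label "Unknown"  ; ff:categoryOf roo:P100246 ; ff:order 3 .

# Radiotherapy type
ncit:C15313 a owl:Class ; rdfs:label "Radiotherapy"      ; ff:categoryOf roo:P100231 ; ff:order 1 .
ncit:C15632 a owl:Class ; rdfs:label "Chemoradiotherapy" ; ff:categoryOf roo:P100231 ; ff:order 2 .

# Survival status (Table-style labels: censored = alive at last follow-up)
ncit:C37987 a owl:Class ; rdfs:label "Censored" ; ff:categoryOf roo:P100028 ; ff:order 1 .
ncit:C28554 a owl:Class ; rdfs:label "Deceased" ; ff:categoryOf roo:P100028 ; ff:order 2 .
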