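table_id,age_group,sex,site,segment,field,printed,curated,justification
t13,adult,male,Clavicle,Ends,b,240,24,"Width 240 mm exceeds the stated database maximum linear dimension of 88 mm; the female analog is 21-24 mm; read as a x10 slip"
t13,adult,male,Clavicle,Ends,c,,12,"Deformed cylinder printed without upper-base axes; shaft minor axes used, mirroring the 15-year pattern where end inner axes equal the shaft axes"
t13,adult,male,Clavicle,Ends,d,,12,"See entry for field c"
t14,adult,female,Clavicle,Ends,c,,10,"Deformed cylinder printed without upper-base axes; female shaft minor axes used"
t14,adult,female,Clavicle,Ends,d,,10,"See entry for field c"
t13,adult,male,Clavicle,Acromial shaft,c,12,,"Stray upper-base axes on a segment printed as a cylinder; the adult shape census (17 cylinders) keeps the printed shape letter, so the stray axes are dropped"
t13,adult,male,Clavicle,Acromial shaft,d,12,,"See entry for field c"
t14,adult,female,Clavicle,Acromial shaft,c,10,,"Stray upper-base axes on a printed cylinder; dropped"
t14,adult,female,Clavicle,Acromial shaft,d,10,,"See entry for field c"
t13,adult,male,Sternum,Manubrium,h,1.3,13,"A 1.3 mm manubrium is anatomically impossible and below the printed 2 mm database minimum (newborn skull); read as a x10 slip"
t13,adult,male,Sternum,Sternum bdoy,h,1.0,10,"Same x10 slip as the manubrium height"
t13,adult,male,Sternum,Sternum bdoy,segment,Sternum bdoy,Sternum body,"Typographic transposition"
t14,adult,female,Sternum,Body,h,0.9,9,"Same x10 slip as the male sternum heights"
t14,adult,female,Sternum,Manubrium,h,1.1,11,"Same x10 slip as the male sternum heights"
t10,10y,any,Humery,Distal end,site,Humery,Humerus,"Site-name normalization; all other tables print Humerus"
t10,10y,any,Humery,Proximal end,site,Humery,Humerus,"Site-name normalization; all other tables print Humerus"
t8,1y,any,Pelvis,Ischium tuberosity,shape,b,c,"The printed 1-year shape census (15 boxes / 13 cylinders) requires one printed box to be a cylinder; the ischium is the pelvic element whose shape class changes most across ages"
t8,1y,any,Pelvis,Ischium tuberosity,cortical,ha:0.4+hb:0.4,lateral:0.4,"Follows the shape reclassification: the covered side faces become the lateral surface"
t8,1y,any,Pelvis,Ilium acetabular part,c,24,,"Stray upper-base axes on a printed cylinder; the 1-year census (10 deformed cylinders) keeps the printed shape letter, so the stray axes are dropped"
t8,1y,any,Pelvis,Ilium acetabular part,d,18,,"See entry for field c"
t8,1y,any,Humerus,Shaft,c,9.1,,"Stray value equal to the lateral axes on a printed cylinder; dropped"
t7,newborn,any,Hand and foot,Precarpal,h,,7.8,"Ellipsoid axes printed shifted one column right (h blank); realigned so the three axes are 7.8 x 12 x 7.8"
t7,newborn,any,Hand and foot,Precarpal,a,7.8,12,"Column realignment; see entry for field h"
t7,newborn,any,Hand and foot,Precarpal,b,12,7.8,"Column realignment; see entry for field h"
t7,newborn,any,Hand and foot,Precarpal,c,7.8,,"Column realignment; see entry for field h"
t14,adult,female,Sacrum,Ala 3-4,c,38.5,,"Stray repeat of b on a prism; dropped"
t14,adult,female,Sacrum,Ala 3-4,cortical,bh:1.5+ab1:1.5,bh:1.5+ch:1.5+abb1:1.5,"Garbled face list repaired to the male row; the adult shape census (one shared prism) requires this row to match the male one"
t14,adult,female,Ribs,5.6.7.8,segment,5.6.7.8,"5,6,7,8","Punctuation normalization to the male row"
t11,15y,any,Ribs,"1, 2",sex_distinct,shared,true,"The printed 15-year shared-segment count (28) requires four printed-identical rows to be sex-specific; the rib groups and the lumbar body are exactly the rows that are sex-specific in the adult tables"
t11,15y,any,Ribs,"11, 12",sex_distinct,shared,true,"See Ribs 1-2 entry"
t11,15y,any,Ribs,"5,6,7,8",sex_distinct,shared,true,"See Ribs 1-2 entry"
t11,15y,any,Vertebra,L- body,sex_distinct,shared,true,"See Ribs 1-2 entry"
t13,adult,any,Scapula,Glenoid,sex_distinct,shared,true,"The printed adult census (23 shared, 17 cylinders) balances only if one printed-identical cylinder row is sex-specific once the Ala 3-4 prism is repaired to shared"
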