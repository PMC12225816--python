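# Default segment multiplicities (n_s) and truncation factors (k_s).
# Matched top-down on (age_group, normalized site, normalized segment fnmatch pattern);
# first hit wins. age_group '*' matches every age. k_s > 1 marks a truncated segment
# (a 30 mm fragment or 30x30 mm plate standing for a larger structure); values derive
# from typical whole-bone dimensions stated in the basis column, anchored to the one
# printed datum: the adult iliac ala plate covers 9 cm^2 of a 91.2 cm^2 segment.
age_group	site	segment_pattern	n_s	k_s	basis
*	Clavicle	ends	4	1	paired bone, both ends in one record
*	Clavicle	acromeonend	2	1	paired bone
*	Clavicle	acromialend	2	1	paired bone
*	Clavicle	sternalend	2	1	paired bone
newborn	Clavicle	shaft	2	1	33 mm model covers the whole 44 mm bone less ends
1y	Clavicle	shaft	2	1	42 mm model covers the 55 mm bone less ends
5y	Clavicle	shaft	2	1.9	80 mm bone less 24 mm ends over 30 mm fragment
10y	Clavicle	body	2	2.2	105 mm bone less 34 mm ends over 30 mm fragment
15y	Clavicle	shaft	2	3.3	140 mm bone less 40 mm ends over 30 mm fragment
adult	Clavicle	acromialshaft	2	1	56 mm model covers the acromial half of the diaphysis
adult	Clavicle	sternalshaft	2	1	56 mm model covers the sternal half of the diaphysis
newborn	Femur	shaft	2	1.2	74 mm bone less 38 mm ends over 30 mm fragment
1y	Femur	shaft	2	2.5	147 mm bone less 72 mm ends over 30 mm fragment
5y	Femur	shaft	2	6.0	280 mm bone less 99 mm ends over 30 mm fragment
*	Femur	*	2	1	paired bone
newborn	Humerus	shaft	2	1.3	64 mm bone less 26 mm ends over 30 mm fragment
1y	Humerus	shaft	2	2.4	105 mm bone less 32 mm ends over 30 mm fragment
5y	Humerus	shaft	2	5.1	200 mm bone less 47 mm ends over 30 mm fragment
*	Humerus	*	2	1	paired bone
*	Radius and ulna	end	8	1	two bones, two ends each, both sides
newborn	Radius and ulna	shaft	4	1.1	56 mm mean bone less 24 mm ends over 30 mm fragment
1y	Radius and ulna	shaft	4	1.8	85 mm mean bone less 32 mm ends over 30 mm fragment
5y	Radius and ulna	shaft	4	2.9	140 mm mean bone less 52 mm ends over 30 mm fragment
*	Hand and foot	precarpal	4	1	talus and calcaneus, both feet
*	Hand and foot	tubebones	76	1	19 tubular bones per hand and per foot, both sides
newborn	Tibia and fibula	tibiashaft	2	1.3	72 mm bone less 34 mm ends over 30 mm fragment
1y	Tibia and fibula	tibiashaft	2	2.0	120 mm bone less 61 mm ends over 30 mm fragment
5y	Tibia and fibula	tibiashaft	2	4.9	215 mm bone less 68 mm ends over 30 mm fragment
newborn	Tibia and fibula	fibulashaft	2	2.3	68 mm bone over 30 mm fragment
1y	Tibia and fibula	fibulashaft	2	3.7	110 mm bone over 30 mm fragment
5y	Tibia and fibula	fibulabody	2	6.7	200 mm bone over 30 mm fragment
10y	Tibia and fibula	fibulaends	4	1	two ends, both sides
*	Tibia and fibula	*	2	1	paired bone
15y	Pelvis	iliacala	2	8.9	ala plate 9 cm^2 of roughly 80 cm^2 segment
adult	Pelvis	iliacala	2	10.1	ala plate 9 cm^2 of the printed 91.2 cm^2 segment
*	Pelvis	iliaccrest	2	8.5	30 mm fragment of a roughly 255 mm crest
*	Pelvis	iliacdorsal*	2	3.3	30x30 plate of a roughly 30 cm^2 dorsal segment
1y	Pelvis	iliumflatpart*	2	1.4	half-ala plate 9 cm^2 of roughly 12.5 cm^2
5y	Pelvis	iliumflatpart*	2	2.5	half-ala plate 9 cm^2 of roughly 22.5 cm^2
10y	Pelvis	iliumflatpart*	2	3.9	half-ala plate 9 cm^2 of roughly 35 cm^2
*	Pelvis	*	2	1	paired bone
newborn	Ribs	ribs	24	1.8	mean rib arc 55 mm over 30 mm fragment
1y	Ribs	ribs	24	2.5	mean rib arc 75 mm over 30 mm fragment
5y	Ribs	ribs	24	4.0	mean rib arc 120 mm over 30 mm fragment
10y	Ribs	ribs	24	5.3	mean rib arc 160 mm over 30 mm fragment
*	Ribs	12	4	5.3	ribs 1-2 arc about 160 mm, both sides
*	Ribs	1112	4	6.0	ribs 11-12 arc about 180 mm, both sides
*	Ribs	34910	8	8.3	ribs 3,4,9,10 arc about 250 mm, both sides
*	Ribs	5678	8	10	ribs 5-8 arc about 300 mm, both sides
*	Sacrum	body23	2	1	two vertebral levels
*	Sacrum	body45	2	1	two vertebral levels
*	Sacrum	ala34	4	1	two levels, both sides
*	Sacrum	sacralala*	2	1	both sides
*	Sacrum	ala*	2	1	both sides
*	Sacrum	pedicle*	2	1	both sides
*	Sacrum	bodyala*	1	1	full-width slab includes both alae
*	Sacrum	body*	1	1	single vertebral level
5y	Scapula	lateralmargin	2	2.0	lateral border about 60 mm over 30 mm fragment
10y	Scapula	lateralmargin	2	2.6	lateral border about 78 mm over 30 mm fragment
15y	Scapula	lateralmargin	2	3.3	lateral border about 99 mm over 30 mm fragment
adult	Scapula	lateralmargin	2	3.5	lateral border about 105 mm over 30 mm fragment
*	Scapula	*	2	1	paired bone
newborn	Skull	*	1	21	cranial vault about 190 cm^2 over the 9 cm^2 plate
1y	Skull	*	1	37	cranial vault about 330 cm^2 over the 9 cm^2 plate
5y	Skull	*	1	49	cranial vault about 440 cm^2 over the 9 cm^2 plate
10y	Skull	*	1	53	cranial vault about 480 cm^2 over the 9 cm^2 plate
15y	Skull	*	1	57	cranial vault about 510 cm^2 over the 9 cm^2 plate
adult	Skull	*	1	58	cranial vault about 520 cm^2 over the 9 cm^2 plate
*	Sternum	manubrium	1	2.2	manubrium about 20 cm^2 over the 9 cm^2 plate
adult	Sternum	*	1	3.5	sternal body about 31 cm^2 over the 9 cm^2 plate
5y	Sternum	sternum	1	1.1	sternum about 10 cm^2 over the 9 cm^2 plate
10y	Sternum	sternum	1	1.7	sternum about 15 cm^2 over the 9 cm^2 plate
15y	Sternum	sternum	1	2.7	sternum about 24 cm^2 over the 9 cm^2 plate
*	Vertebra	c1mass	2	1	paired lateral masses of the atlas
*	Vertebra	c2body	1	1	axis body
*	Vertebra	cervicalbody2	1	1	axis body
*	Vertebra	c37body	5	1	vertebrae C3-C7
*	Vertebra	cbody37	5	1	vertebrae C3-C7
*	Vertebra	cervicallateral1	2	1	paired lateral masses of the atlas
*	Vertebra	cbody	7	1	seven cervical vertebrae
*	Vertebra	cervicalvertebrabody	7	1	seven cervical vertebrae
*	Vertebra	lbody	5	1	five lumbar vertebrae
*	Vertebra	lumbarvertebrabody	5	1	five lumbar vertebrae
*	Vertebra	tbody	12	1	twelve thoracic vertebrae
*	Vertebra	thoracicvertebrabody	12	1	twelve thoracic vertebrae
*	Vertebra	lspinous*	5	1	one per lumbar vertebra
*	Vertebra	ltransverse*	10	1	two per lumbar vertebra
*	Vertebra	lsuperior*	10	1	two per lumbar vertebra
*	Vertebra	llamina*	10	1	two per lumbar vertebra
*	Vertebra	tspinous*	12	1	one per thoracic vertebra
*	Vertebra	ttransverse*	24	1	two per thoracic vertebra
*	Vertebra	tsuperior*	24	1	two per thoracic vertebra
*	Vertebra	tlamina*	24	1	two per thoracic vertebra
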