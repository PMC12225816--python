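age_group	sex	sites	am_fraction
newborn	any	Femur	6.7
newborn	any	Humerus	4.5
newborn	any	Sacrum	4.4
newborn	any	Tibia and fibula	7.1
newborn	any	Pelvis	11.4
newborn	any	Skull	28.2
newborn	any	Clavicle	0.7
newborn	any	Scapula	2.3
newborn	any	Ribs	7.1
newborn	any	Radius and ulna	2.4
newborn	any	Hand and foot	10.8
newborn	any	Cervical vertebrae	1.7
newborn	any	Thoracic vertebrae	7.2
newborn	any	Lumbar vertebrae	5.5
1y	any	Femur	8.1
1y	any	Humerus	5.2
1y	any	Sacrum	5.1
1y	any	Tibia and fibula	8.7
1y	any	Pelvis	13.1
1y	any	Skull	28.7
1y	any	Clavicle	0.9
1y	any	Scapula	2.7
1y	any	Ribs	8.2
1y	any	Radius and ulna	2.6
1y	any	Cervical vertebrae	2.1
1y	any	Thoracic vertebrae	8.3
1y	any	Lumbar vertebrae	6.4
5y	any	Femur	13.5
5y	any	Humerus	4.8
5y	any	Sacrum	5.7
5y	any	Tibia and fibula	9.3
5y	any	Pelvis	13.5
5y	any	Skull	18.1
5y	any	Clavicle	0.9
5y	any	Scapula	2.8
5y	any	Ribs	9.1
5y	any	Radius and ulna	2.1
5y	any	Sternum	1.8
5y	any	Cervical vertebrae	2.3
5y	any	Thoracic vertebrae	9.2
5y	any	Lumbar vertebrae	7.0
10y	any	Femur	15.7
10y	any	Humerus	4.1
10y	any	Sacrum	6.8
10y	any	Tibia and fibula	5.6
10y	any	Pelvis	15.8
10y	any	Skull	12.8
10y	any	Clavicle	0.9
10y	any	Scapula	2.9
10y	any	Ribs	11.0
10y	any	Sternum	2.1
10y	any	Cervical vertebrae	2.7
10y	any	Thoracic vertebrae	11.0
10y	any	Lumbar vertebrae	8.5
15y	any	Femur	11.3
15y	any	Humerus	3.8
15y	any	Sacrum	8.5
15y	any	Pelvis	18.6
15y	any	Skull	10.2
15y	any	Clavicle	1.0
15y	any	Scapula	3.3
15y	any	Ribs	13.7
15y	any	Sternum	1.8
15y	any	Cervical vertebrae	3.3
15y	any	Thoracic vertebrae	13.8
15y	any	Lumbar vertebrae	10.6
adult	any	Femur	5.95
adult	any	Humerus	3.6
adult	any	Sacrum	7.48
adult	any	Pelvis	23.2
adult	any	Skull	6.2
adult	any	Clavicle;Scapula;Ribs	15.3
adult	any	Sternum	1.8
adult	any	Cervical vertebrae	3.5
adult	any	Thoracic vertebrae	17.5
adult	any	Lumbar vertebrae	15.5
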