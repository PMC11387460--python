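cohort,block,label,count,percent_printed
cetirizine,sex,Female,14250,50.80
cetirizine,sex,Male,7505,26.75
cetirizine,sex,Unknown,6296,22.44
cetirizine,reporter,Consumer,21571,76.90
cetirizine,reporter,Physician,2080,7.42
cetirizine,reporter,Other health-professional,1794,6.40
cetirizine,reporter,Pharmacist,1700,6.06
cetirizine,reporter,Lawyer,15,0.05
cetirizine,reporter,Registered nurse,1,0.00
cetirizine,reporter,Unknown,890,3.17
cetirizine,outcomes,Other serious,6735,65.44
cetirizine,outcomes,Hospitalization,2057,19.99
cetirizine,outcomes,Disability,468,4.55
cetirizine,outcomes,Life threatening,468,4.55
cetirizine,outcomes,Death,337,3.27
cetirizine,outcomes,Congenital anomaly,189,1.84
cetirizine,outcomes,Permanent impairment/damage,38,0.37
cetirizine,countries,United States,20218,79.74
cetirizine,countries,United Kingdom,1957,7.72
cetirizine,countries,France,674,2.66
cetirizine,countries,Germany,417,1.64
cetirizine,countries,Italy,374,1.47
cetirizine,countries,Canada,371,1.46
cetirizine,countries,Netherlands,187,0.74
cetirizine,countries,Spain,114,0.45
cetirizine,countries,Singapore,104,0.41
cetirizine,countries,Turkey,84,0.33
cetirizine,countries,Japan,75,0.30
cetirizine,countries,India,71,0.28
cetirizine,countries,Belgium,67,0.26
cetirizine,countries,Russia,52,0.21
cetirizine,countries,Australia,51,0.20
cetirizine,countries,Others,540,2.13
cetirizine,route,Oral,15161,54.10
cetirizine,route,Transplacental,190,0.68
cetirizine,route,Topical,13,0.05
cetirizine,route,Others,12659,45.17
loratadine,sex,Female,15322,53.62
loratadine,sex,Male,9270,32.44
loratadine,sex,Unknown,3981,13.93
loratadine,reporter,Consumer,25667,89.83
loratadine,reporter,Physician,719,2.52
loratadine,reporter,Other health-professional,1245,4.36
loratadine,reporter,Pharmacist,524,1.83
loratadine,reporter,Lawyer,9,0.03
loratadine,reporter,Registered nurse,1,0.00
loratadine,reporter,Unknown,408,1.43
loratadine,outcomes,Other serious,2418,62.02
loratadine,outcomes,Hospitalization,983,25.21
loratadine,outcomes,Disability,96,2.46
loratadine,outcomes,Life threatening,162,4.15
loratadine,outcomes,Death,177,4.54
loratadine,outcomes,Congenital anomaly,22,0.56
loratadine,outcomes,Permanent impairment/damage,41,1.05
loratadine,countries,United States,25359,94.49
loratadine,countries,United Kingdom,549,2.05
loratadine,countries,France,51,0.19
loratadine,countries,Canada,102,0.38
loratadine,countries,Netherlands,86,0.32
loratadine,countries,Japan,77,0.29
loratadine,countries,Australia,214,0.80
loratadine,countries,China,114,0.42
loratadine,countries,Others,287,1.07
loratadine,route,Oral,20458,71.64
loratadine,route,Transplacental,24,0.08
loratadine,route,Ophthalmic,17,0.06
loratadine,route,Others,8057,28.21
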