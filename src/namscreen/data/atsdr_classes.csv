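chemical,chem_class,cas
Lead nitrate,inorganic,10099-74-8
Mercuric chloride,inorganic,7487-94-7
Cadmium chloride,inorganic,10108-64-2
Potassium chromate (VI),inorganic,7789-00-6
Cobalt chloride,inorganic,7646-79-9
Nickel chloride,inorganic,7718-54-9
Zinc chloride,inorganic,7646-85-7
Benzo(b)fluoranthene,PAH,205-99-2
Benzo(a)anthracene,PAH,56-55-3
Naphthalene,PAH,91-20-3
Fluoranthene,PAH,206-44-0
Acenaphthene,PAH,83-32-9
"p,p'-DDT",pesticide,50-29-3
Dieldrin,pesticide,60-57-1
Aldrin,pesticide,309-00-2
"p,p'-DDD",pesticide,72-54-8
Heptachlor,pesticide,76-44-8
Lindane,pesticide,58-89-9
Disulfoton,pesticide,298-04-4
Endrin,pesticide,72-20-8
Diazinon,pesticide,333-41-5
Endosulfan,pesticide,115-29-7
Heptachlor epoxide,pesticide,1024-57-3
"o,p'-DDT",pesticide,789-02-6
Methoxychlor,pesticide,72-43-5
Chlorpyrifos,pesticide,2921-88-2
"2,4-dinitrophenol",pesticide,51-28-5
Ethion,pesticide,563-12-2
Azinphos-methyl,pesticide,86-50-0
Dicofol,pesticide,115-32-2
Parathion,pesticide,56-38-2
Trifluralin,pesticide,1582-09-8
Benzidine,industrial,92-87-5
Pentachlorophenol,industrial,87-86-5
"2,4,6-trichlorophenol",industrial,88-06-2
"2,4-dinitrotoluene",industrial,121-14-2
"2-Methyl-4,6-dinitrophenol",industrial,534-52-1
"1,2,3-Trichlorobenzene",industrial,87-61-6
"2,4,5-Trichlorophenol",industrial,95-95-4
p-Cresol,industrial,106-44-5
Dibutyl phthalate,phthalate,84-74-2
Di(2-ethylhexyl) phthalate,phthalate,117-81-7
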