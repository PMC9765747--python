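# Seed mapping of CAZyme families to a representative EC activity and broad
# substrate classes (animal_carbohydrate, plant_cell_wall, starch_glycogen,
# peptidoglycan, sucrose_fructan). Editable; multiple classes are
# comma-separated. ec may be blank for families with heterogeneous
# activities.
family	ec	substrate_classes
GH1	3.2.1.21	plant_cell_wall
GH2	3.2.1.23	animal_carbohydrate,plant_cell_wall
GH3	3.2.1.21	animal_carbohydrate,plant_cell_wall
GH4	3.2.1.22	plant_cell_wall
GH5	3.2.1.4	plant_cell_wall
GH13	3.2.1.1	starch_glycogen
GH18	3.2.1.14	animal_carbohydrate
GH20	3.2.1.52	animal_carbohydrate
GH23	3.2.1.17	peptidoglycan
GH25	3.2.1.17	peptidoglycan
GH26	3.2.1.78	plant_cell_wall
GH29	3.2.1.51	animal_carbohydrate,plant_cell_wall
GH31	3.2.1.20	plant_cell_wall
GH32	3.2.1.26	sucrose_fructan
GH33	3.2.1.18	animal_carbohydrate
GH36	3.2.1.22	plant_cell_wall
GH38	3.2.1.24	animal_carbohydrate
GH43	3.2.1.37	animal_carbohydrate,plant_cell_wall
GH51	3.2.1.55	plant_cell_wall
GH73	3.2.1.17	peptidoglycan
GH77	2.4.1.25	starch_glycogen
GH78	3.2.1.40	plant_cell_wall
GH84	3.2.1.52	animal_carbohydrate
GH92	3.2.1.24	animal_carbohydrate
GH95	3.2.1.51	animal_carbohydrate,plant_cell_wall
GH97	3.2.1.20	starch_glycogen
GH109	3.2.1.49	animal_carbohydrate
GH127	3.2.1.185	plant_cell_wall
PL1	4.2.2.2	plant_cell_wall
PL8	4.2.2.1	animal_carbohydrate
PL9	4.2.2.2	plant_cell_wall
CE1	3.1.1.72	plant_cell_wall
CBM50		peptidoglycan
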