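# Default hazard-network structure over the literature-database node set.
# State discretisations follow the published case-table conventions:
# half-open [low, high) numeric bins, ">x" meaning [x, inf).
# Wiring: nanoparticle -> hazard -> each descriptor (tree-shaped classifier
# orientation); CPTs are uniform placeholders to be learned from data.
nodes:
  - name: nanoparticle
    states: [TiO2, Ag, ZnO]
    category: physchem
  - name: shape
    states: [Sphere, Irregular, Elongated, Amorph]
    category: physchem
  - name: dissolution
    states: ["0-25%", "25-50%", "50-75%", "75-100%"]
    category: physchem
  - name: surface_area
    states: ["0-15", "15-51", "51-101.25", "101.25-189", "189-2025"]
    category: physchem
  - name: surface_charge
    states: ["from -50 to -25", "from -25 to 0", "0-25", "25-50"]
    category: physchem
  - name: surface_coatings
    states: [None, PVP, Citrate, Hydroxyl, AHPP, Silianes-aluminium,
             Triethoxycapryl silane, Other]
    category: physchem
  - name: surface_reactivity
    states: [Low, Medium, High]
    category: physchem
  - name: aggregation
    states: [Low, Medium, High]
    category: physchem
  - name: particle_size
    states: ["0-10", "10-50", "50-100", ">100"]
    category: physchem
  - name: administration_route
    states: [Oral, Inhalation, Injection, Intravenous]
    category: experimental
  - name: study_type
    states: [In vitro, In vivo]
    category: experimental
  - name: hazard
    states: [None, Low, Medium, High]
    category: hazard
edges:
  - [nanoparticle, hazard]
  - [hazard, shape]
  - [hazard, dissolution]
  - [hazard, surface_area]
  - [hazard, surface_charge]
  - [hazard, surface_coatings]
  - [hazard, surface_reactivity]
  - [hazard, aggregation]
  - [hazard, particle_size]
  - [hazard, administration_route]
  - [hazard, study_type]
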