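# Gastric-cancer risk-factor ontology.
#
# The root "risk factor" class has four category subclasses — stomach
# condition, personal feature, systemic condition, diet food — joined by
# IS-A edges; each dataset feature maps to a feature-attribute concept under
# its category.  Non-hierarchical "cause" edges link each category, and the
# individually established causal factors, to the disease concept.
concepts:
  - name: gastric cancer
  - name: risk factor
  - name: stomach condition
    parent: risk factor
  - name: personal feature
    parent: risk factor
  - name: systemic condition
    parent: risk factor
  - name: diet food
    parent: risk factor
  # personal features
  - name: sex
    parent: personal feature
    kind: feature-attribute
  - name: blood group
    parent: personal feature
    kind: feature-attribute
  - name: smoking
    parent: personal feature
    kind: feature-attribute
  - name: alcohol consumption
    parent: personal feature
    kind: feature-attribute
  - name: exposed to chemicals
    parent: personal feature
    kind: feature-attribute
  - name: bmi
    parent: personal feature
    kind: feature-attribute
  - name: motility
    parent: personal feature
    kind: feature-attribute
  - name: age
    parent: personal feature
    kind: feature-attribute
  # diet foods
  - name: salt consumption
    parent: diet food
    kind: feature-attribute
  - name: consumption of vegetable
    parent: diet food
    kind: feature-attribute
  - name: consumption of smoked food
    parent: diet food
    kind: feature-attribute
  - name: milk consumption
    parent: diet food
    kind: feature-attribute
  - name: fast food consumption
    parent: diet food
    kind: feature-attribute
  - name: consumption of fried foods
    parent: diet food
    kind: feature-attribute
  - name: fruit consumption
    parent: diet food
    kind: feature-attribute
  - name: food storage container
    parent: diet food
    kind: feature-attribute
  - name: dish cooking
    parent: diet food
    kind: feature-attribute
  # systemic conditions
  - name: history of allergy
    parent: systemic condition
    kind: feature-attribute
  - name: family history of cancer
    parent: systemic condition
    kind: feature-attribute
  - name: family history of gastric cancer
    parent: systemic condition
    kind: feature-attribute
  - name: history of cardiovascular disease
    parent: systemic condition
    kind: feature-attribute
  - name: general status of cancer
    parent: systemic condition
    kind: feature-attribute
  # stomach conditions
  - name: history of gastric reflux
    parent: stomach condition
    kind: feature-attribute
  - name: history of stomach surgery
    parent: stomach condition
    kind: feature-attribute
  - name: history of gastritis
    parent: stomach condition
    kind: feature-attribute
  - name: history of stomach infection
    parent: stomach condition
    kind: feature-attribute
  - name: mucosa status
    parent: stomach condition
    kind: feature-attribute
  - name: cancer site
    parent: stomach condition
    kind: feature-attribute

relations:
  - [stomach condition, cause, gastric cancer]
  - [personal feature, cause, gastric cancer]
  - [systemic condition, cause, gastric cancer]
  - [diet food, cause, gastric cancer]
  - [history of stomach surgery, cause, gastric cancer]
  - [history of gastritis, cause, gastric cancer]
  - [history of stomach infection, cause, gastric cancer]
  - [history of gastric reflux, cause, gastric cancer]
  - [smoking, cause, gastric cancer]
  - [salt consumption, cause, gastric cancer]
  - [family history of gastric cancer, cause, gastric cancer]

feature_map:
  Sex: sex
  Blood group: blood group
  Smoking: smoking
  Alcohol consumption: alcohol consumption
  Exposed to chemicals: exposed to chemicals
  BMI: bmi
  Motility: motility
  Age: age
  Salt consumption: salt consumption
  Consumption of vegetable: consumption of vegetable
  Consumption of smoked food: consumption of smoked food
  Milk consumption: milk consumption
  Fast food consumption: fast food consumption
  Consumption of fried foods: consumption of fried foods
  Fruit consumption: fruit consumption
  Food storage container: food storage container
  Dish cooking: dish cooking
  History of allergy: history of allergy
  Family history of cancer: family history of cancer
  Family history of gastric cancer: family history of gastric cancer
  History of cardiovascular disease: history of cardiovascular disease
  Gastric cancer: gastric cancer
  General status of cancer: general status of cancer
  History of gastric reflux: history of gastric reflux
  History of stomach surgery: history of stomach surgery
  History of gastritis: history of gastritis
  History of stomach infection: history of stomach infection
  Mucosa status: mucosa status
  Cancer site: cancer site
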