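# Relatedness fixture for the 5-feature worked example.
#
# Relatedness here is defined entirely by explicit pair overrides: every
# feature is related to the disease outcome, and stomach-surgery history is
# additionally related to smoking, milk consumption, and family history of
# gastric cancer.  All other pairs are unrelated (no graph edges exist, so
# the direct/indirect/cohort meta-rules find nothing).
concepts:
  - name: gastric cancer
  - name: history of stomach surgery
    kind: feature-attribute
  - name: milk consumption
    kind: feature-attribute
  - name: smoking
    kind: feature-attribute
  - name: family history of gastric cancer
    kind: feature-attribute

feature_map:
  Gastric cancer: gastric cancer
  History of stomach surgery: history of stomach surgery
  Milk consumption: milk consumption
  Smoking: smoking
  Family history of gastric cancer: family history of gastric cancer

overrides:
  - [Gastric cancer, History of stomach surgery, true]
  - [Gastric cancer, Milk consumption, true]
  - [Gastric cancer, Smoking, true]
  - [Gastric cancer, Family history of gastric cancer, true]
  - [History of stomach surgery, Smoking, true]
  - [History of stomach surgery, Milk consumption, true]
  - [History of stomach surgery, Family history of gastric cancer, true]
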