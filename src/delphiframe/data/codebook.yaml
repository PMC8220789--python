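# Criterion inventory for medical-device design in low-resource settings:
# 7 domains, 28 criteria, with each criterion's final framework status and
# whether it belongs to a discriminatory (device-comparable) domain.
# Cost and lifetime criteria are informative only: comparing them needs a
# reference device, so they are non-discriminatory.
domains:
  - id: "1"
    label: "User type"
  - id: "2"
    label: "Health technology management (HTM)"
  - id: "3"
    label: "Design"
  - id: "4"
    label: "Reliance on external factors"
  - id: "5"
    label: "Material"
  - id: "6"
    label: "Cost"
  - id: "7"
    label: "Lifetime"
criteria:
  - {id: "1.1", domain: "1", label: "End users' background", status: retained, discriminatory: true}
  - {id: "1.2", domain: "1", label: "Easiness of use", status: excluded_reliability, discriminatory: true}
  - {id: "1.3", domain: "1", label: "Training needs", status: retained, discriminatory: true}
  - {id: "1.4", domain: "1", label: "User's understanding of the technical and clinical impact", status: retained, discriminatory: true}
  - {id: "2.1", domain: "2", label: "Need for consumables", status: retained, discriminatory: true}
  - {id: "2.2", domain: "2", label: "Need for spare parts", status: retained, discriminatory: true}
  - {id: "2.3", domain: "2", label: "Installation requirements", status: retained, discriminatory: true}
  - {id: "2.4", domain: "2", label: "Maintenance complexity", status: retained, discriminatory: true}
  - {id: "2.5", domain: "2", label: "Maintenance frequency", status: retained, discriminatory: true}
  - {id: "2.6", domain: "2", label: "Compatible consumables/spare parts", status: retained, discriminatory: true}
  - {id: "3.1", domain: "3", label: "Portability, compactness, robustness", status: retained, discriminatory: true}
  - {id: "3.2", domain: "3", label: "Limiting the number of components/spare parts", status: retained, discriminatory: true}
  - {id: "3.3", domain: "3", label: "Reusability", status: retained, discriminatory: true}
  - {id: "4.1", domain: "4", label: "Reliance on power sources", status: retained, discriminatory: true}
  - {id: "4.2", domain: "4", label: "Reliance on water distribution", status: retained, discriminatory: true}
  - {id: "4.3", domain: "4", label: "Reliance on medical location air", status: retained, discriminatory: true}
  - {id: "4.4", domain: "4", label: "Need for sample preparation", status: retained, discriminatory: true}
  - {id: "4.5", domain: "4", label: "Understanding/stating the dependence of the MD from the medical location characteristics", status: excluded_importance, discriminatory: true}
  - {id: "4.6", domain: "4", label: "Resilience to dusty environments", status: a_posteriori, discriminatory: true}
  - {id: "4.7", domain: "4", label: "Resilience to high-temperature environments", status: a_posteriori, discriminatory: true}
  - {id: "4.8", domain: "4", label: "Resilience to high-humidity environments", status: a_posteriori, discriminatory: true}
  - {id: "5.1", domain: "5", label: "Durability of the material", status: retained, discriminatory: true}
  - {id: "5.2", domain: "5", label: "Robustness of the material", status: retained, discriminatory: true}
  - {id: "6.1", domain: "6", label: "Maintenance costs", status: retained, discriminatory: false}
  - {id: "6.2", domain: "6", label: "Running costs", status: retained, discriminatory: false}
  - {id: "6.3", domain: "6", label: "Initial cost", status: retained, discriminatory: false}
  - {id: "7.1", domain: "7", label: "Lifetime of MD parts/components", status: retained, discriminatory: false}
  - {id: "7.2", domain: "7", label: "MD lifetime", status: retained, discriminatory: false}
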