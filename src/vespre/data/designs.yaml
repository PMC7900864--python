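# Line-item cost fixtures for the three study designs compared by the
# original VESPRE sepsis deployment: the VESPRE infrastructure itself, a
# prehospital coordinator-led cohort, and a hypothetical coordinator-led
# cohort performing the same activities as VESPRE for the same 1027
# patients. Amounts are US dollars-and-cents strings (parsed exactly).
#
# The prehospital study total was reported without a category split, so it
# is carried as a single laboratory-category item. The VESPRE laboratory
# category is split into the -80C freezer purchase and the remaining
# supplies/staff so that the category total is preserved.
designs:
  - name: VESPRE
    n_patients: 1027
    items:
      - label: electronic alert build
        category: project_management
        amount: "13500.00"
      - label: sequential alert capability updates
        category: project_management
        amount: "1380.00"
      - label: 21 cu ft -80C freezer
        category: laboratory
        amount: "13035.00"
      - label: laboratory supplies and staff (excl. freezer)
        category: laboratory
        amount: "9682.50"
      - label: data management
        category: data_management
        amount: "1820.00"
  - name: prehospital_cohort
    n_patients: 787
    items:
      - label: coordinator-collected sampling (category split not reported)
        category: laboratory
        amount: "99073.46"
  - name: hypothetical_coordinator
    n_patients: 1027
    items:
      - label: electronic alert
        category: project_management
        amount: "14880.00"
      - label: preplanning
        category: project_management
        amount: "9300.00"
      - label: recruitment, screening, and enrollment coordinator core
        category: project_management
        amount: "196200.00"
      - label: laboratory supplies and staff
        category: laboratory
        amount: "22717.50"
      - label: data management
        category: data_management
        amount: "1820.00"
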