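# Regimen taxonomy for line-of-therapy classification.
#
# drug_to_component maps claim-level drug codes (synthetic tokens here; swap in
# local receipt codes for real data) to regimen components, so brand/generic
# duplicates of one component never trigger a new line.  Categories are matched
# hierarchically in the order listed: the first category whose component
# requirements are a subset of the line's components wins.  Conditioning
# regimens (MINE/LEED/MCEC/MEAM) classify as conditioning-before-auto-SCT only
# when an autologous transplant occurs within the line; otherwise the line is
# counted as other chemotherapy without rituximab.

drug_to_component:
  RTX-A: rituximab
  RTX-B: rituximab          # second code for the same component (brand/generic)
  OBZ-1: obinutuzumab
  MOG-1: mogamulizumab
  CPA-1: cyclophosphamide
  DOX-1: doxorubicin
  VCR-1: vincristine
  PSL-1: prednisolone
  DEX-1: dexamethasone
  ETP-1: etoposide
  IFO-1: ifosfamide
  CBP-1: carboplatin
  ARA-1: cytarabine
  GEM-1: gemcitabine
  CDDP-1: cisplatin
  BEN-1: bendamustine
  MPSL-1: methylprednisolone
  MIT-1: mitoxantrone
  MES-1: mesna
  MEL-1: melphalan
  RAN-1: ranimustine
  NOVEL-1: novel_agent
  UNSPEC-1: unspecified_chemo

# Components that identify "other immunotherapy" for the rituximab-combination
# exclusion rule.
immunotherapy_components: [obinutuzumab, mogamulizumab]

# Components counted as chemotherapy for the other-chemo fall-through.
# unspecified_chemo is deliberately absent: lines made only of unspecified
# agents classify as not-otherwise-specified.
chemo_components:
  [cyclophosphamide, doxorubicin, vincristine, prednisolone, dexamethasone,
   etoposide, ifosfamide, carboplatin, cytarabine, gemcitabine, cisplatin,
   bendamustine, methylprednisolone, mitoxantrone, mesna, melphalan,
   ranimustine, novel_agent]

categories:
  - id: r_devic
    label: "R+/-DeVIC-based"
    required: [dexamethasone, etoposide, ifosfamide, carboplatin]
    rituximab: optional
  - id: r_chase
    label: "R-CHASE-based"
    required: [cyclophosphamide, cytarabine, etoposide, dexamethasone]
    rituximab: required
  - id: gdp
    label: "GDP-based with or without R"
    required: [gemcitabine, dexamethasone]
    any_of: [cisplatin, carboplatin]
    rituximab: optional
  - id: r_bendamustine
    label: "R-Bendamustine-based"
    required: [bendamustine]
    rituximab: required
  - id: r_epoch
    label: "R-EPOCH"
    required: [etoposide, prednisolone, vincristine, cyclophosphamide, doxorubicin]
    rituximab: required
  - id: r_eshap
    label: "R-ESHAP-based"
    required: [etoposide, cytarabine, cisplatin, methylprednisolone]
    rituximab: required
  - id: eshap
    label: "ESHAP-based"
    required: [etoposide, cytarabine, cisplatin, methylprednisolone]
    rituximab: optional
  - id: r_ice
    label: "R-ICE-based"
    required: [ifosfamide, carboplatin, etoposide]
    rituximab: required
  - id: r_dhap
    label: "R-DHAP-based"
    required: [dexamethasone, cytarabine, cisplatin]
    rituximab: required

conditioning_sets:
  mine: [mitoxantrone, ifosfamide, mesna, etoposide]
  leed: [melphalan, cyclophosphamide, etoposide, dexamethasone]
  mcec: [ranimustine, carboplatin, etoposide, cyclophosphamide]
  meam: [ranimustine, etoposide, cytarabine, melphalan]

fallback_labels:
  other_r: "Other R-based"
  conditioning_auto_sct: "Conditioning before auto-SCT"
  other_chemo_without_r: "Other chemotherapy without R"
  nos: "Not otherwise specified"
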