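# Canonical Naranjo ADR probability scale weights.
# Each question scores (yes, no, unknown); "unknown" always scores 0.
# Edit a copy of this file and pass it via --weights to override.
questions:
  - id: previous_conclusive_reports
    text: Are there previous conclusive reports on this reaction?
    "yes": 1
    "no": 0
    "unknown": 0
  - id: event_after_drug
    text: Did the adverse event appear after the suspected drug was administered?
    "yes": 2
    "no": -1
    "unknown": 0
  - id: improved_on_withdrawal
    text: Did the adverse reaction improve when the drug was discontinued or a specific antagonist was administered?
    "yes": 1
    "no": 0
    "unknown": 0
  - id: reappeared_on_rechallenge
    text: Did the adverse reaction reappear when the drug was readministered?
    "yes": 2
    "no": -1
    "unknown": 0
  - id: alternative_causes
    text: Are there alternative causes that could on their own have caused the reaction?
    "yes": -1
    "no": 2
    "unknown": 0
  - id: placebo_reaction
    text: Did the reaction reappear when a placebo was given?
    "yes": -1
    "no": 1
    "unknown": 0
  - id: toxic_drug_concentration
    text: Was the drug detected in blood or other fluids in concentrations known to be toxic?
    "yes": 1
    "no": 0
    "unknown": 0
  - id: dose_response
    text: Was the reaction more severe when the dose was increased, or less severe when the dose was decreased?
    "yes": 1
    "no": 0
    "unknown": 0
  - id: previous_similar_reaction
    text: Did the patient have a similar reaction to the same or similar drugs in any previous exposure?
    "yes": 1
    "no": 0
    "unknown": 0
  - id: objective_evidence
    text: Was the adverse event confirmed by any objective evidence?
    "yes": 1
    "no": 0
    "unknown": 0
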