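# Prompt wording is configuration, not code: replace this file (or point
# load_prompts at another) to change phrasing without a code release.
detection:
  instruction: |
    You are reviewing the hospital chart of one admitted patient. Decide whether
    this patient experienced a pulmonary embolism as a hospital-acquired adverse
    event: a pulmonary embolism that developed after admission (it was not
    present on admission) and is linked to the hospital stay.
  evidence_header: "EVIDENCE FROM CLINICAL NOTES:"
  discharge_header: "DISCHARGE INFORMATION:"
  empty_evidence: "No PE-related text was retrieved for this patient."
  output_instruction: |
    Answer "yes" or "no" in your first sentence, then justify your answer using
    only the evidence above.
discharge:
  instruction: |
    Read the discharge summary below and extract the following six sections.
    Return the result as a single JSON object whose keys are exactly:
    "reason for hospitalization", "significant findings",
    "procedures and treatments", "medical history", "discharge condition",
    "patient and family instructions".
    Use an empty string for any section that is absent.
  summary_header: "DISCHARGE SUMMARY:"
  summary_footer: "END OF DISCHARGE SUMMARY"
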