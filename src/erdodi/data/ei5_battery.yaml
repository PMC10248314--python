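# Default five-component Erdodi Index (EI-5) battery.
# Cut values are the published level-1/2/3 failure cutoffs for each
# embedded validity indicator; bands trichotomize the summed index as
# Pass <= 1, Borderline 2-3, Fail >= 4.
name: EI-5
pass_max: 1
borderline_max: 3
missing_policy: error
components:
  - name: CD
    direction: low_fails
    cuts: [6, 5, 4]
    units: age-corrected scaled score (WAIS Coding)
    valid_range: [1, 19]
    granularity: 1
  - name: RCFT_Copy
    direction: low_fails
    cuts: [29.0, 25.0, 22.0]
    units: raw score (Rey Complex Figure Test copy trial)
    valid_range: [0, 36]
    granularity: 0.5
  - name: FMS_WCST
    direction: high_fails
    cuts: [3, 4, 5]
    units: raw count (failures to maintain set, WCST)
    valid_range: [0, 30]
    granularity: 1
  - name: RDS
    direction: low_fails
    cuts: [7, 6, 5]
    units: raw score (Reliable Digit Span)
    valid_range: [0, 16]
    granularity: 1
  - name: RH_CVLT
    direction: low_fails
    cuts: [12, 11, 10]
    units: raw score (CVLT yes/no recognition hits)
    valid_range: [0, 16]
    granularity: 1
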