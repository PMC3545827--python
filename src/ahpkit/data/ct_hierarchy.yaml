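goal:
  id: ct_scanner
  label: Select a new CT scanner
categories:
- id: performance
  label: PERFORMANCE
  children:
  - id: spatial_resolution
    label: Spatial Resolution
  - id: speed_run
    label: Speed Run
  - id: processing_software
    label: Processing software
- id: safety
  label: SAFETY
  children:
  - id: radiation_dose
    label: Patient radiation dose
  - id: patient_monitoring
    label: Patient Monitoring
  - id: contrast_medium
    label: Contrast medium control
- id: usability
  label: USABILITY
  children:
  - id: personnel_education
    label: Personnel Education
  - id: user_friendly_gui
    label: User-friendly GUI
  - id: interoperability
    label: Interoperability
- id: technical_issues
  label: TECHNICAL ISSUES
  children:
  - id: technical_assistance
    label: Technical Assistance
  - id: maintenance
    label: Maintenance
  - id: data_storing
    label: Data Storing
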