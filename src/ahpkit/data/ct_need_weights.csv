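responder_id,category_id,need_id,LW,GW
radiology,performance,spatial_resolution,0.32,0.07
radiology,performance,speed_run,0.46,0.10
radiology,performance,processing_software,0.22,0.05
radiology,safety,radiation_dose,0.33,0.16
radiology,safety,patient_monitoring,0.33,0.16
radiology,safety,contrast_medium,0.33,0.16
radiology,usability,personnel_education,0.69,0.13
radiology,usability,user_friendly_gui,0.23,0.04
radiology,usability,interoperability,0.08,0.02
radiology,technical_issues,technical_assistance,0.33,0.04
radiology,technical_issues,maintenance,0.33,0.04
radiology,technical_issues,data_storing,0.33,0.04
ear_surgery,performance,spatial_resolution,0.64,0.28
ear_surgery,performance,speed_run,0.11,0.05
ear_surgery,performance,processing_software,0.26,0.11
ear_surgery,safety,radiation_dose,0.33,0.11
ear_surgery,safety,patient_monitoring,0.33,0.11
ear_surgery,safety,contrast_medium,0.33,0.11
ear_surgery,usability,personnel_education,0.52,0.07
ear_surgery,usability,user_friendly_gui,0.18,0.03
ear_surgery,usability,interoperability,0.30,0.04
ear_surgery,technical_issues,technical_assistance,0.33,0.03
ear_surgery,technical_issues,maintenance,0.33,0.03
ear_surgery,technical_issues,data_storing,0.33,0.03
neurology,performance,spatial_resolution,0.48,0.19
neurology,performance,speed_run,0.11,0.04
neurology,performance,processing_software,0.41,0.16
neurology,safety,radiation_dose,0.33,0.10
neurology,safety,patient_monitoring,0.33,0.10
neurology,safety,contrast_medium,0.33,0.10
neurology,usability,personnel_education,0.32,0.07
neurology,usability,user_friendly_gui,0.22,0.05
neurology,usability,interoperability,0.46,0.10
neurology,technical_issues,technical_assistance,0.22,0.02
neurology,technical_issues,maintenance,0.32,0.03
neurology,technical_issues,data_storing,0.46,0.05
emergency_neurology,performance,spatial_resolution,0.43,0.08
emergency_neurology,performance,speed_run,0.43,0.08
emergency_neurology,performance,processing_software,0.14,0.03
emergency_neurology,safety,radiation_dose,0.14,0.08
emergency_neurology,safety,patient_monitoring,0.58,0.33
emergency_neurology,safety,contrast_medium,0.28,0.16
emergency_neurology,usability,personnel_education,0.48,0.08
emergency_neurology,usability,user_friendly_gui,0.11,0.02
emergency_neurology,usability,interoperability,0.41,0.07
emergency_neurology,technical_issues,technical_assistance,0.66,0.05
emergency_neurology,technical_issues,maintenance,0.16,0.01
emergency_neurology,technical_issues,data_storing,0.18,0.01
emergency,performance,spatial_resolution,0.30,0.05
emergency,performance,speed_run,0.52,0.09
emergency,performance,processing_software,0.18,0.03
emergency,safety,radiation_dose,0.18,0.11
emergency,safety,patient_monitoring,0.66,0.40
emergency,safety,contrast_medium,0.16,0.10
emergency,usability,personnel_education,0.33,0.04
emergency,usability,user_friendly_gui,0.33,0.04
emergency,usability,interoperability,0.33,0.04
emergency,technical_issues,technical_assistance,0.46,0.04
emergency,technical_issues,maintenance,0.32,0.03
emergency,technical_issues,data_storing,0.22,0.02
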