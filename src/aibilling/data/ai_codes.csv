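code_id,level,specialty,description,points
AI-101,I,Radiology-X-ray,Assistive AI triage of chest X-ray images (flags abnormal vs. normal exams for radiologist),50
AI-102,I,Ultrasound imaging,Assistive AI feature detection in ultrasound (highlights organ contours or lesions for physician),60
AI-201,II,Laboratory diagnostics,Augmentative AI analysis of lab results (interprets complex patterns and suggests potential diagnoses or need for further tests),80
AI-202,II,Pathology-Histology,Augmentative AI slide review support (marks suspicious cells/regions on digitized pathology slides for pathologist review),150
AI-301,III,Cardiology-ECG,Autonomous AI interpretation of ECG with preliminary report (physician oversight available for confirmation),100
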