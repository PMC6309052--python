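now with newly diagnosed dcis recurrence
she was found to have an ipsilateral breast tumor recurrence
is currently receiving chemotherapy for her recurrent breast cancer
biopsy proven recurrence in the {lat} breast
recurrent dcis at the lumpectomy site
she has a chest wall recurrence after mastectomy
pathology confirmed recurrent carcinoma at the scar
locoregional recurrence after breast conserving therapy
she underwent re excision for recurrent disease
tumor recurrence at the mastectomy site confirmed on biopsy
history of recurrent breast cancer now with a new {lat} breast recurrence
she presents with an in breast tumor recurrence diagnosed in {year}
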