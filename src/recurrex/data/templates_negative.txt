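pt very concerned and anxious as some of her friends have been diagnosed with recurrent breast cancer
no evidence of recurrent breast cancer in the {lat} breast
no dcis recurrence at the lumpectomy site
we will rule out a chest wall recurrence after mastectomy
no recurrent carcinoma at the scar on pathology
imaging negative for locoregional recurrence after breast conserving therapy
no tumor recurrence at the mastectomy site on biopsy
she denies any palpable recurrence in the {lat} breast
follow up evaluation for possible in breast tumor recurrence
we discussed the risk of recurrence after re excision
concern for recurrence was not confirmed on biopsy
she is dealing well with fear of recurrence
no evidence of recurrence on imaging today
we discussed the risk of a new {lat} breast recurrence
mammogram was unremarkable
biopsy proven recurrence was ruled out
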