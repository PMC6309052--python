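patient is doing well today
vital signs are stable
she will follow up in three months
blood pressure is well controlled
she continues her daily walking routine
medication list reviewed and updated
she reports good energy and appetite
physical exam within expected limits
family accompanied her to the visit today
she received the influenza vaccine
laboratory values reviewed with the patient
sleep has improved since the last visit
diet and exercise counseling provided
return to clinic as scheduled
her incision is healing nicely
she resumed her usual activities
mood is stable and affect appropriate
pain well controlled with current regimen
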