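# synthetic positive concept set: cui	preferred_name
C1997028	History of malignant neoplasm of breast
C1387407	Personal history of primary malignant neoplasm of breast
C2945760	Recurrent
C0278493	Recurrent breast cancer
C0920420	Cancer recurrence
C1458156	Recurrent Malignant Neoplasm
C0235653	Malignant neoplasm of female breast
C0277556	Recurrent disease
C1512083	Ductal
C0007124	Noninfiltrating Intraductal Carcinoma
C0222600	Right breast
C0205090	Right
C0262512	History of present illness
C4042789	Right-Sided Breast Neoplasms
C0006142	Malignant neoplasm of breast
C3900001	Local recurrence of malignant neoplasm
C3900002	Chest wall recurrence
C3900003	Ipsilateral breast tumor recurrence
C3900004	Ipsilateral breast
C3900005	Tumor recurrence
C3900006	Recurrence
C3900007	Infiltrating ductal carcinoma
C3900008	Infiltrating lobular carcinoma
C3900009	Left breast
C3900010	Left
C3900011	Mastectomy
C3900012	Lumpectomy
C3900013	Breast-conserving therapy
C3900014	Radiotherapy
C3900015	Chemotherapy
C3900016	Excision
C3900017	Re-excision
C3900018	Biopsy
C3900019	Chest wall
C3900020	Carcinoma
C3900021	Recurrent carcinoma
C3900022	Breast tumor
C3900023	Tumor
C3900024	Relapse
C3900025	Locoregional recurrence
C3900026	Nodal recurrence
C3900027	Skin recurrence
C3900028	Scar recurrence
C3900029	Mastectomy site
C3900030	Lumpectomy bed
C3900031	Biopsy-proven recurrence
C3900032	In-breast tumor recurrence
C3900033	Recurrent ductal carcinoma in situ
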