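# synthetic dictionary lexicon: cui	preferred_name	surface_form	score
C1997028	History of malignant neoplasm of breast	history of recurrent breast cancer	1.0
C1997028	History of malignant neoplasm of breast	history of breast cancer recurrence	1.0
C1387407	Personal history of primary malignant neoplasm of breast	history of recurrent breast	1.0
C1387407	Personal history of primary malignant neoplasm of breast	personal history of breast carcinoma	1.0
C2945760	Recurrent	recurrent	1.0
C0278493	Recurrent breast cancer	recurrent breast ca	1.0
C0278493	Recurrent breast cancer	breast cancer recurrence	1.0
C0278493	Recurrent breast cancer	recurrence of breast cancer	1.0
C0920420	Cancer recurrence	cancer recurrence	1.0
C0920420	Cancer recurrence	recurrence of the cancer	1.0
C1458156	Recurrent Malignant Neoplasm	recurrent malignancy	1.0
C1458156	Recurrent Malignant Neoplasm	recurrent malignant neoplasm	1.0
C0235653	Malignant neoplasm of female breast	breast malignancy	1.0
C0235653	Malignant neoplasm of female breast	malignancy of the breast	1.0
C0277556	Recurrent disease	recurrent disease	1.0
C0277556	Recurrent disease	disease recurrence	1.0
C1512083	Ductal	ductal	1.0
C0007124	Noninfiltrating Intraductal Carcinoma	dcis	1.0
C0007124	Noninfiltrating Intraductal Carcinoma	ductal carcinoma in situ	1.0
C0007124	Noninfiltrating Intraductal Carcinoma	intraductal carcinoma	1.0
C0222600	Right breast	right breast	1.0
C0205090	Right	right	1.0
C0262512	History of present illness	history of present illness	1.0
C4042789	Right-Sided Breast Neoplasms	right sided breast cancer	1.0
C4042789	Right-Sided Breast Neoplasms	right sided breast tumor	1.0
C0006142	Malignant neoplasm of breast	breast carcinoma	1.0
C0006142	Malignant neoplasm of breast	carcinoma of the breast	1.0
C3900001	Local recurrence of malignant neoplasm	local recurrence	1.0
C3900001	Local recurrence of malignant neoplasm	locally recurrent	1.0
C3900002	Chest wall recurrence	chest wall recurrence	1.0
C3900002	Chest wall recurrence	chest wall breast cancer recurrence	1.0
C3900003	Ipsilateral breast tumor recurrence	ipsilateral breast tumor recurrence	1.0
C3900004	Ipsilateral breast	ipsilateral breast	1.0
C3900005	Tumor recurrence	tumor recurrence	1.0
C3900005	Tumor recurrence	recurrence of the tumor	1.0
C3900006	Recurrence	recurrence	1.0
C3900007	Infiltrating ductal carcinoma	infiltrating ductal carcinoma	1.0
C3900007	Infiltrating ductal carcinoma	invasive ductal carcinoma	1.0
C3900008	Infiltrating lobular carcinoma	infiltrating lobular carcinoma	1.0
C3900008	Infiltrating lobular carcinoma	invasive lobular carcinoma	1.0
C3900009	Left breast	left breast	1.0
C3900010	Left	left	1.0
C3900011	Mastectomy	mastectomy	1.0
C3900012	Lumpectomy	lumpectomy	1.0
C3900013	Breast-conserving therapy	breast conserving therapy	1.0
C3900013	Breast-conserving therapy	breast conserving surgery	1.0
C3900014	Radiotherapy	radiotherapy	1.0
C3900014	Radiotherapy	radiation therapy	1.0
C3900015	Chemotherapy	chemotherapy	1.0
C3900015	Chemotherapy	chemo	1.0
C3900016	Excision	excision	1.0
C3900017	Re-excision	re excision	1.0
C3900018	Biopsy	biopsy	1.0
C3900018	Biopsy	core needle biopsy	1.0
C3900019	Chest wall	chest wall	1.0
C3900020	Carcinoma	carcinoma	1.0
C3900021	Recurrent carcinoma	recurrent carcinoma	1.0
C3900022	Breast tumor	breast tumor	1.0
C3900023	Tumor	tumor	1.0
C3900024	Relapse	relapse	1.0
C3900024	Relapse	relapsed	1.0
C3900025	Locoregional recurrence	locoregional recurrence	1.0
C3900025	Locoregional recurrence	local regional recurrence	1.0
C3900026	Nodal recurrence	nodal recurrence	1.0
C3900026	Nodal recurrence	axillary recurrence	1.0
C3900027	Skin recurrence	skin recurrence	1.0
C3900028	Scar recurrence	scar recurrence	1.0
C3900028	Scar recurrence	recurrence at the scar	1.0
C3900029	Mastectomy site	mastectomy site	1.0
C3900030	Lumpectomy bed	lumpectomy bed	1.0
C3900030	Lumpectomy bed	lumpectomy site	1.0
C3900031	Biopsy-proven recurrence	biopsy proven recurrence	1.0
C3900032	In-breast tumor recurrence	in breast tumor recurrence	1.0
C3900033	Recurrent ductal carcinoma in situ	dcis recurrence	1.0
C3900033	Recurrent ductal carcinoma in situ	recurrent dcis	1.0
C3999001	The	the	1.0
C3999002	Then	then	1.0
C3999003	To	to	1.0
C3999004	After	after	1.0
C3999005	With	with	1.0
C3999006	Her	her	1.0
C3999007	She	she	1.0
C3999008	Was	was	1.0
C3999009	Who	who	1.0
C3999010	Now	now	1.0
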