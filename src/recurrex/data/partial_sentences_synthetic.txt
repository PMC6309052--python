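# synthetic development partial sentences, one per line
history of recurrent breast cancer
after her chest wall breast cancer recurrence excision
now with newly diagnosed dcis recurrence
she was found to have an ipsilateral breast tumor recurrence
is currently receiving chemotherapy for her recurrent breast cancer
she initially received breast conserving therapy with radiotherapy for a right breast cancer in 1990 and now she presents with a right sided pt1b n0 sn infiltrating lobular carcinoma
female with a history of left breast stage iiic infiltrating ductal carcinoma who was treated with breast conserving surgery and adjuvant chemo radiation in 2010 who was recently diagnosed with a cancer in the ipsilateral breast
biopsy proven recurrence in the left breast
recurrent dcis at the lumpectomy site
new local recurrence at the mastectomy site
she has a chest wall recurrence after mastectomy
recurrence of breast cancer at the lumpectomy bed
now with biopsy proven local recurrence of the right breast
recurrent invasive ductal carcinoma of the left breast
recurrent invasive lobular carcinoma in the right breast
she presents with an in breast tumor recurrence
tumor recurrence at the mastectomy site confirmed on biopsy
pathology confirmed recurrent carcinoma at the scar
scar recurrence noted after her excision
she developed a nodal recurrence in the axilla
axillary recurrence confirmed by core needle biopsy
skin recurrence over the mastectomy site
locoregional recurrence after breast conserving therapy
local regional recurrence treated with radiotherapy
she underwent re excision for recurrent disease
disease recurrence in the ipsilateral breast
recurrent malignancy of the right breast
recurrent malignant neoplasm of the left breast
breast malignancy recurred at the original site
malignancy of the breast with recurrence in the chest wall
history of breast cancer recurrence treated with chemotherapy
personal history of breast carcinoma with new recurrence
history of present illness notable for recurrent breast ca
recurrence of the cancer in her right breast
cancer recurrence at the lumpectomy site
recurrence of the tumor after radiation therapy
she was treated with lumpectomy for her recurrent tumor
relapse of breast carcinoma in the chest wall
she relapsed with a dcis recurrence
right sided breast cancer recurrence after mastectomy
right sided breast tumor recurrence at the scar
carcinoma of the breast with local recurrence
locally recurrent ductal carcinoma in situ
intraductal carcinoma recurrence at the lumpectomy bed
recurrent breast ca found on core needle biopsy
new recurrence at the scar after re excision
she presents with recurrence at the scar of her mastectomy
chest wall recurrence treated with radiation therapy
in breast tumor recurrence after breast conserving therapy
biopsy proven local recurrence of the left breast
biopsy proven local recurrence of the right breast
biopsy proven local recurrence of the ipsilateral breast
recurrent carcinoma in the left breast
recurrent carcinoma in the right breast
recurrent carcinoma in the ipsilateral breast
tumor recurrence in the left breast
tumor recurrence in the right breast
tumor recurrence in the ipsilateral breast
cancer recurrence in the left breast after lumpectomy
cancer recurrence in the right breast after lumpectomy
cancer recurrence in the ipsilateral breast after lumpectomy
disease recurrence in the left breast after mastectomy
disease recurrence in the right breast after mastectomy
disease recurrence in the ipsilateral breast after mastectomy
dcis recurrence in the left breast
dcis recurrence in the right breast
dcis recurrence in the ipsilateral breast
skin recurrence of the left chest wall
skin recurrence of the right chest wall
skin recurrence of the ipsilateral chest wall
nodal recurrence after left mastectomy
nodal recurrence after right mastectomy
nodal recurrence after ipsilateral mastectomy
recurrent malignancy in the left breast after radiotherapy
recurrent malignancy in the right breast after radiotherapy
recurrent malignancy in the ipsilateral breast after radiotherapy
relapse of carcinoma in the left breast
relapse of carcinoma in the right breast
relapse of carcinoma in the ipsilateral breast
she developed a recurrence in the left breast in 2012
she developed a recurrence in the right breast in 2012
she developed a recurrence in the ipsilateral breast in 2012
recurrence of breast cancer in the left breast after excision
recurrence of breast cancer in the right breast after excision
recurrence of breast cancer in the ipsilateral breast after excision
locoregional recurrence in the left chest wall
locoregional recurrence in the right chest wall
locoregional recurrence in the ipsilateral chest wall
recurrent invasive ductal carcinoma in the left breast after lumpectomy
recurrent invasive ductal carcinoma in the right breast after lumpectomy
recurrent invasive ductal carcinoma in the ipsilateral breast after lumpectomy
in breast tumor recurrence of the left breast
in breast tumor recurrence of the right breast
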