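indication_pt,group
Ovarian cancer,Ovarian cancer
Ovarian cancer recurrent,Ovarian cancer
Ovarian cancer metastatic,Ovarian cancer
Ovarian epithelial cancer,Ovarian cancer
Fallopian tube cancer,Fallopian tube carcinoma
Fallopian tube cancer metastatic,Fallopian tube carcinoma
Uterine cancer,Uterine carcinoma
Endometrial cancer,Uterine carcinoma
Cervix carcinoma,Cervix carcinoma
Cervix cancer,Cervix carcinoma
Female reproductive neoplasm,Other gynecological malignant neoplasm
Vulval cancer,Other gynecological malignant neoplasm
Breast cancer,Breast cancer
Breast cancer metastatic,Breast cancer
Prostate cancer,Prostate cancer
Prostate cancer metastatic,Prostate cancer
Lung neoplasm malignant,Lung cancer
Non-small cell lung cancer,Lung cancer
Small cell lung cancer,Lung cancer
Pancreatic carcinoma,Digestive system malignant neoplasm
Pancreatic carcinoma metastatic,Digestive system malignant neoplasm
Colorectal cancer,Digestive system malignant neoplasm
Gastric cancer,Digestive system malignant neoplasm
Hepatic cancer,Digestive system malignant neoplasm
Peritoneal neoplasm,Peritoneal malignant neoplasm
Bladder cancer,Bladder cancer
Malignant neoplasm progression,Neoplasm with unclear primary sites
Neoplasm malignant,Neoplasm with unclear primary sites
Metastatic neoplasm,Neoplasm with unclear primary sites
Product used for unknown indication,Neoplasm with unclear primary sites
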