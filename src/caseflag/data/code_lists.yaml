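# Code lists defining each case-ascertainment flag.
#
# Each flag names the source dataset it is extracted from and the set of
# codes that trigger it.  Diagnosis flags use ICD-10-AM site codes for
# malignant neoplasm of breast; the surgery flags use ICD-10-AM procedure
# codes; radiotherapy uses MBS item codes; medicines uses PBS item codes
# (all therapies subsidised only for breast cancer in women; only the
# 500 mg medroxyprogesterone preparation qualifies, hence item 2728N only).
registry_diagnosis:
  dataset: registry
  codes: [C50.0, C50.1, C50.2, C50.3, C50.4, C50.5, C50.6, C50.7, C50.8, C50.9]
diagnosis:
  dataset: hospital_dx
  codes: [C50.0, C50.1, C50.2, C50.3, C50.4, C50.5, C50.6, C50.7, C50.8, C50.9]
mastectomy:
  dataset: hospital_proc
  codes: [31518-00, 31518-01, 31524-00, 31524-01]
lumpectomy:
  dataset: hospital_proc
  codes: [31500-00, 31500-01, 31503-00, 31503-01, 31506-00,
          31506-01, 31509-00, 31509-01, 31512-00, 31512-01]
radiotherapy:
  dataset: service_claim
  codes: ['15221', '15236', '15251', '15266']
medicines:
  dataset: prescription_claim
  codes: [2109B, 2110C, 8216K,           # tamoxifen, toremifene
          8179L, 8506Q, 8245Y,           # anastrozole, exemestane, letrozole
          1452M,                          # goserelin
          4632T, 4639E, 4650R, 4703M,    # trastuzumab
          7264H, 7265J, 7266K, 7267L,
          9148L,                          # lapatinib
          2728N]                          # medroxyprogesterone 500 mg
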