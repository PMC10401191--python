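# Recommendation catalogue: code -> display text shown to the health worker.
HTN_SEVERE_URGENT: "This woman has evidence of severe hypertension. Call ambulance and refer patient to hospital urgently."
HTN_REFER: "This woman has raised blood pressure or an elevated shock index. Refer her to the primary health centre for review."
ANEMIA_SEVERE_URGENT: "This woman has severe anaemia. Call ambulance and refer patient to hospital urgently."
ANEMIA_MOD_REFER: "This woman has moderate to severe anaemia. Refer her to the primary health centre for treatment."
ANEMIA_MILD_COUNSEL: "This woman has mild anaemia. Counsel on iron and folic acid supplementation and diet."
DM_OVERT_URGENT: "This woman's glucose tolerance test suggests overt diabetes. Refer her to hospital urgently."
GDM_REFER: "This woman's glucose tolerance test suggests gestational diabetes. Refer her to the primary health centre."
PROMPT_GDM_SCREEN: "This woman has not been screened for gestational diabetes. Arrange screening."
PROMPT_OGTT: "No oral glucose tolerance test is on record for this pregnancy. Arrange an OGTT."
PROMPT_REPEAT_OGTT: "No repeat postpartum oral glucose tolerance test is on record. Arrange a repeat OGTT."
PROMPT_IFA: "Iron and folic acid supplements have not been supplied. Arrange supply."
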