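fine_code,category
group_inservice,group_inservice
group_preservice,group_preservice
self_study,self_study
eov,eov
peer_to_peer,peer_to_peer
community_support,community_support
patient_support,patient_support
infrastructure,infrastructure
hcp_financial_incentives,hcp_financial_incentives
financing_other_incentives,financing_other_incentives
regulation_governance,regulation_governance
group_problem_solving,group_problem_solving
supervision,supervision
other_management,other_management
printed_materials_standalone,printed_materials_standalone
ict,ict
placebo,placebo
inservice_workshop,group_inservice
inservice_clinical_course,group_inservice
refresher_course,group_inservice
preservice_curriculum_module,group_preservice
preservice_semester_course,group_preservice
self_study_modules,self_study
distance_learning_packet,self_study
academic_detailing,eov
outreach_visit_expert,eov
peer_education,peer_to_peer
cascade_training,peer_to_peer
community_health_education,community_support
social_marketing,community_support
patient_leaflets,patient_support
patient_home_visits,patient_support
drug_supply,infrastructure
equipment_provision,infrastructure
performance_based_pay,hcp_financial_incentives
bonus_payment,hcp_financial_incentives
user_fee_reduction,financing_other_incentives
insurance_scheme,financing_other_incentives
accreditation,regulation_governance
licensing_inspection,regulation_governance
collaborative_improvement,group_problem_solving
quality_improvement_team,group_problem_solving
routine_supervision,supervision
audit_with_feedback,supervision
benchmarking,supervision
self_assessment,other_management
group_process_other,other_management
job_aid,printed_materials_standalone
wall_chart,printed_materials_standalone
pamphlet_for_hcp,printed_materials_standalone
sms_reminders,ict
computerised_decision_aid,ict
ehealth_tool,ict
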